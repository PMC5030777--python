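"""RPM normalisation, zero imputation, fold change, and a noise-
distribution differential-expression call.

The significance model is the empirical-counting form of the NOISeq
idea: within-group library pairs provide a cloud of per-gene noise
points (M_n = log2 ratio, D_n = absolute difference); a gene's between-
group signal point (M_A, D_A) gets

    prob = #{noise points with |M_n| < |M_A| and D_n < D_A} / #points

(strict inequality on both axes). A gene is significant when
|M_A| >= 1.0 and prob > 0.8. The published NOISeq package adds
resampling and kernel smoothing on top of this; only the counting model
is implemented here.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table convention)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def normalize_rpm(
    raw_counts: pd.DataFrame, library_totals: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """RPM = raw count / total raw count x 1,000,000, per library.

    ``library_totals`` defaults to the column sums of ``raw_counts``;
    pass the clean-read totals explicitly when the matrix holds only a
    subset of the counted tags.
    """
    totals = (
        pd.Series(library_totals, dtype="float64")[raw_counts.columns]
        if library_totals is not None
        else raw_counts.sum(axis=0).astype("float64")
    )
    if (totals <= 0).any():
        raise ValueError("library totals must be > 0")
    return raw_counts.astype("float64").div(totals, axis=1) * 1_000_000


def impute_zero(matrix: pd.DataFrame, floor: float = 0.01) -> pd.DataFrame:
    """Replace exact zeros with ``floor`` (default 0.01); leave everything
    else untouched."""
    out = matrix.copy()
    out[out == 0.0] = floor
    return out


def log2_fold_change(mt_value: float, wt_value: float) -> float:
    """M = log2(MT / WT); inputs must be post-imputation (> 0)."""
    if mt_value <= 0 or wt_value <= 0:
        raise ValueError("fold change needs positive (imputed) expressions")
    return math.log2(mt_value / wt_value)


@dataclass
class NoiseModel:
    """Within-group noise points (|M| is taken at comparison time)."""

    m: np.ndarray
    d: np.ndarray

    def __len__(self) -> int:
        return len(self.m)


def build_noise_model(
    matrix: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> NoiseModel:
    """Noise points from every within-group unordered library pair and
    every gene; the matrix must already be imputed."""
    ms, ds = [], []
    any_pair = False
    for libs in groups.values():
        for a, b in combinations(libs, 2):
            any_pair = True
            va = matrix[a].to_numpy(dtype="float64")
            vb = matrix[b].to_numpy(dtype="float64")
            if (va <= 0).any() or (vb <= 0).any():
                raise ValueError("noise model requires imputed (positive) values")
            ms.append(np.log2(va / vb))
            ds.append(np.abs(va - vb))
    if not any_pair:
        raise ValueError("no group has two libraries")
    return NoiseModel(np.concatenate(ms), np.concatenate(ds))


def noiseq_prob(m_a: float, d_a: float, model: NoiseModel) -> float:
    """Fraction of noise points strictly dominated on both axes."""
    if len(model) == 0:
        raise ValueError("empty noise model")
    below = (np.abs(model.m) < abs(m_a)) & (model.d < d_a)
    return float(below.sum()) / len(model)


@dataclass
class DEResult:
    mirna: str
    control_avg: float  # WT mean RPM
    treat_avg: float  # MT mean RPM
    m: float  # log2(treat/control)
    d: float  # |control - treat|
    prob: float
    significant: bool


def run_de(
    matrix: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    treat: str = "MT",
    control: str = "WT",
    floor: float = 0.01,
    m_threshold: float = 1.0,
    prob_threshold: float = 0.8,
) -> list[DEResult]:
    """Impute, build the noise model, and score every gene."""
    imputed = impute_zero(matrix, floor)
    model = build_noise_model(imputed, groups)
    results = []
    for gene in imputed.index:
        t = float(imputed.loc[gene, list(groups[treat])].mean())
        c = float(imputed.loc[gene, list(groups[control])].mean())
        m = log2_fold_change(t, c)
        d = abs(c - t)
        prob = noiseq_prob(m, d, model)
        results.append(
            DEResult(
                mirna=str(gene),
                control_avg=c,
                treat_avg=t,
                m=m,
                d=d,
                prob=prob,
                significant=is_significant(m, prob, m_threshold, prob_threshold),
            )
        )
    return results


def is_significant(
    m: float, prob: float, m_threshold: float = 1.0, prob_threshold: float = 0.8
) -> bool:
    """|M| >= 1.0 (inclusive) with prob > 0.8 (strict)."""
    return abs(m) >= m_threshold and prob > prob_threshold


def call_de(
    results: Sequence[DEResult],
    m_threshold: float = 1.0,
    prob_threshold: float = 0.8,
) -> list[DEResult]:
    return [r for r in results if is_significant(r.m, r.prob, m_threshold, prob_threshold)]


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    """Report table mirroring the published layout; M rounded to 2 dp
    half away from zero."""
    return pd.DataFrame(
        {
            "miRNA": [r.mirna for r in results],
            "WT_RPM": [r.control_avg for r in results],
            "MT_RPM": [r.treat_avg for r in results],
            "Prob": [r.prob for r in results],
            "log2(MT/WT)": [round_half_away(r.m, 2) for r in results],
            "significant": [r.significant for r in results],
        }
    ).set_index("miRNA")
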