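"""Artificial minimum/maximum individuals and fixed-range centile scaling.

The *absolute minimum* individual is homozygous for the effect allele at
every protective (beta < 0) SNP and carries zero effect alleles elsewhere;
the *absolute maximum* individual is the opposite.  Their sum-mode scores
bound every achievable score, anchoring a fixed scale that is cut into 100
equal-width centile bins; each cohort's scores are then placed on that
scale and tabulated per bin by case/control status.

Absolutes are defined for sum scoring only: average mode normalizes by a
per-sample denominator and would break the fixed-range guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import ScoreFile
from .scoring_stats import PRSResult


@dataclass
class AbsoluteRange:
    min_score: float
    max_score: float
    n_bins: int = 100

    def __post_init__(self) -> None:
        if self.min_score > self.max_score:
            raise ValueError("min_score exceeds max_score")
        self.degenerate = self.min_score == self.max_score

    @property
    def bin_edges(self) -> np.ndarray:
        return centile_bins(self)


@dataclass
class CentileTable:
    table: pd.DataFrame  # centile (1..100), n_cases, n_controls


def make_absolutes(scores: ScoreFile) -> tuple[np.ndarray, np.ndarray]:
    """Effect-allele dosage vectors of the minimum and maximum individuals.

    min: dosage 2 where beta < 0, else 0; max: dosage 2 where beta > 0,
    else 0 (a beta of exactly 0 contributes nothing either way).
    """
    if len(scores) == 0:
        raise ValueError("empty score file")
    beta = scores.table["beta"].to_numpy()
    d_min = np.where(beta < 0, 2, 0)
    d_max = np.where(beta > 0, 2, 0)
    return d_min, d_max


def absolute_range(scores: ScoreFile, n_bins: int = 100) -> AbsoluteRange:
    """Sum-mode score range attainable under a score file."""
    d_min, d_max = make_absolutes(scores)
    beta = scores.table["beta"].to_numpy()
    return AbsoluteRange(float(d_min @ beta), float(d_max @ beta), n_bins=n_bins)


def centile_bins(rng: AbsoluteRange) -> np.ndarray:
    """n_bins+1 equal-interval edges over [min_score, max_score].

    Bins are half-open [e_k, e_{k+1}) except the last, which is closed so
    the maximum score itself lands in the top bin.
    """
    if rng.degenerate:
        raise ValueError("degenerate range: min_score == max_score")
    return rng.min_score + np.arange(rng.n_bins + 1) * (rng.max_score - rng.min_score) / rng.n_bins


def centile_table(prs: PRSResult, rng: AbsoluteRange) -> CentileTable:
    """Per-centile case/control counts of a cohort's scores on the absolute scale.

    A score outside [min_score, max_score] certifies a scoring/range
    inconsistency and raises.
    """
    edges = centile_bins(rng)
    ev = prs.evaluable()
    s = ev.scores
    if len(s) and (s.min() < rng.min_score or s.max() > rng.max_score):
        raise ValueError("score outside the absolute range: scoring/range inconsistency")
    # np.digitize with right=False puts e_k <= s < e_{k+1} into bin k+1
    bins = np.digitize(s, edges[1:-1])  # 0..n_bins-1
    y = ev.phenotype
    rows = []
    for b in range(rng.n_bins):
        inb = bins == b
        rows.append(
            {"centile": b + 1, "n_cases": int((inb & (y == 1)).sum()), "n_controls": int((inb & (y == 0)).sum())}
        )
    return CentileTable(pd.DataFrame(rows))


def upper_tail_ppv(table: CentileTable, threshold_centile: int) -> float | None:
    """Proportion of cases among samples in centile bins >= threshold.

    Returns None (flagged undefined) when no sample scores that high.
    """
    if not 1 <= threshold_centile <= len(table.table):
        raise ValueError("threshold centile out of range")
    upper = table.table[table.table["centile"] >= threshold_centile]
    n_cases = int(upper["n_cases"].sum())
    n_total = n_cases + int(upper["n_controls"].sum())
    if n_total == 0:
        return None
    return n_cases / n_total


def plot_centiles(table: CentileTable, path, title: str = "") -> None:
    """Bar chart of cases (black) and controls (light gray) per centile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = table.table
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(t["centile"], t["n_controls"], color="lightgray", label="controls")
    ax.bar(t["centile"], t["n_cases"], bottom=t["n_controls"], color="black", label="cases")
    ax.set_xlabel("risk-score centile")
    ax.set_ylabel("samples")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
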