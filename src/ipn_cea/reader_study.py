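"""Synthetic multi-reader classification study.

Stands in for the multi-reader validation study that the stratification
probabilities were derived from: each of ``n_readers`` readers assigns
each nodule (of known truth) to a high/intermediate/low cancer-probability
class, under both strategies, with class probabilities given by a true
stratification matrix.  Reads are independent across readers and nodules —
the model consumes only the marginal class frequencies, which is exactly
how the published probabilities were computed from counts.

Defaults emulate a 12-reader, 300-nodule study; the malignant/benign
split of the cohort is an explicit knob (150/150 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    RISK_CLASSES,
    STRATEGIES,
    TRUTHS,
    ParameterError,
    ParameterSet,
)

__all__ = [
    "ReaderStudyCounts",
    "simulate_reader_study",
    "counts_to_probs",
    "counts_to_dataframe",
    "DEFAULT_N_READERS",
    "DEFAULT_N_MALIGNANT",
    "DEFAULT_N_BENIGN",
]

DEFAULT_N_READERS = 12
DEFAULT_N_MALIGNANT = 150
DEFAULT_N_BENIGN = 150


@dataclass(frozen=True)
class ReaderStudyCounts:
    """Classification counts per (strategy, truth, assigned class)."""

    counts: dict[tuple[str, str, str], int]
    n_readers: int
    n_nodules: dict[str, int]

    def total_reads(self, strategy: str, truth: str) -> int:
        return sum(self.counts[(strategy, truth, c)] for c in RISK_CLASSES)

    def __post_init__(self) -> None:
        for s in STRATEGIES:
            for t in TRUTHS:
                expected = self.n_readers * self.n_nodules[t]
                got = self.total_reads(s, t)
                if got != expected:
                    raise ParameterError(
                        f"reads for ({s}, {t}) total {got}, expected {expected}"
                    )


def simulate_reader_study(
    true_matrix: dict[tuple[str, str], tuple[float, ...]],
    n_readers: int = DEFAULT_N_READERS,
    n_malignant: int = DEFAULT_N_MALIGNANT,
    n_benign: int = DEFAULT_N_BENIGN,
    seed: int = 0,
) -> ReaderStudyCounts:
    """Draw every (reader, nodule) classification from the true matrix.

    ``true_matrix`` maps (strategy, truth) to (high, intermediate, low)
    assignment probabilities, e.g. ``ParameterSet.stratification_matrix()``.
    """
    if n_readers < 1 or n_malignant < 1 or n_benign < 1:
        raise ParameterError("reader and nodule counts must be >= 1")
    n_nodules = {"malignant": n_malignant, "benign": n_benign}
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str, str], int] = {}
    for strategy in STRATEGIES:
        for truth in TRUTHS:
            row = np.asarray(true_matrix[(strategy, truth)], dtype=float)
            if row.shape != (3,) or abs(row.sum() - 1.0) > 1e-9 or (row < 0).any():
                raise ParameterError(
                    f"invalid stratification row for ({strategy}, {truth}): {row}"
                )
            reads = rng.multinomial(1, row, size=(n_readers, n_nodules[truth]))
            totals = reads.reshape(-1, 3).sum(axis=0)
            for cls, total in zip(RISK_CLASSES, totals):
                counts[(strategy, truth, cls)] = int(total)
    return ReaderStudyCounts(counts, n_readers, n_nodules)


def counts_to_probs(
    counts: ReaderStudyCounts,
) -> dict[tuple[str, str], tuple[float, ...]]:
    """Per-stratum relative class frequencies (rows sum to one exactly)."""
    matrix = {}
    for strategy in STRATEGIES:
        for truth in TRUTHS:
            total = counts.total_reads(strategy, truth)
            if total < 1:
                raise ParameterError(f"empty stratum ({strategy}, {truth})")
            matrix[(strategy, truth)] = tuple(
                counts.counts[(strategy, truth, c)] / total for c in RISK_CLASSES
            )
    return matrix


def counts_to_dataframe(counts: ReaderStudyCounts) -> pd.DataFrame:
    """Long-format table (strategy, truth, class, count) for export."""
    rows = [
        {"strategy": s, "truth": t, "risk_class": c,
         "count": counts.counts[(s, t, c)]}
        for s in STRATEGIES for t in TRUTHS for c in RISK_CLASSES
    ]
    return pd.DataFrame(rows)


def inject_matrix(params: ParameterSet,
                  matrix: dict[tuple[str, str], tuple[float, ...]]) -> ParameterSet:
    """Replace the packaged stratification rows with estimated ones."""
    out = params
    for strategy in STRATEGIES:
        out = out.with_stratification(
            strategy, {t: matrix[(strategy, t)] for t in TRUTHS}
        )
    return out
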