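"""Binned single-cell stimulus-specific information.

For each hidden unit the activation range is divided into bins and a
(category x bin) count table is accumulated over test presentations.
The stimulus-specific information about category ``s`` is

    I(s, R) = sum_r P(r|s) log2( P(r|s) / P(r) )   [bits]

with P(r|s) the row-normalized conditional response distribution and
P(r) the marginal over all presentations — the Kullback-Leibler
divergence between the unit's response distribution given ``s`` and its
marginal response distribution. Terms with P(r|s) = 0 contribute 0.
With equal class priors every value lies in [0, log2(nCat)].

Probabilities are plug-in empirical frequencies with no bias
correction; the finite-sampling bias floor can be characterized with
the label-shuffle null (:func:`shuffled_info_null`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class AnalysisError(ValueError):
    pass


@dataclass
class ActivationMatrix:
    """Responses of one layer's units to a set of test presentations.

    ``responses`` is (n_samples, n_units); ``labels`` holds the digit
    presented on each row and ``conditions`` the modality-presence tag
    ('both', 'visual_only', 'audio_only').
    """

    responses: np.ndarray
    labels: np.ndarray
    conditions: np.ndarray

    def __post_init__(self) -> None:
        if self.responses.ndim != 2:
            raise AnalysisError("responses must be 2-D (samples x units)")
        if len(self.labels) != len(self.responses) or len(self.conditions) != len(self.responses):
            raise AnalysisError("labels/conditions length mismatch")
        if not np.all(np.isfinite(self.responses)):
            raise AnalysisError("responses must be finite")

    @property
    def n_units(self) -> int:
        return self.responses.shape[1]

    def filtered(self, condition_filter: str) -> "ActivationMatrix":
        """Rows matching ``condition_filter`` ('all' keeps everything)."""
        if condition_filter == "all":
            return self
        mask = self.conditions == condition_filter
        if not mask.any():
            raise AnalysisError(f"condition filter {condition_filter!r} selects no samples")
        return ActivationMatrix(self.responses[mask], self.labels[mask],
                                self.conditions[mask])


@dataclass
class BinnedResponseTable:
    """Per-unit (category x bin) response counts with derived probabilities."""

    counts: np.ndarray
    bin_edges: np.ndarray
    unit_id: int = 0
    categories: Sequence = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise AnalysisError("counts must be 2-D (categories x bins)")
        if np.any(self.counts < 0):
            raise AnalysisError("counts must be nonnegative")
        if len(self.bin_edges) != self.counts.shape[1] + 1:
            raise AnalysisError("bin_edges must have n_bins + 1 entries")
        if not list(self.categories):
            self.categories = list(range(self.counts.shape[0]))

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def p_r_given_s(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1, keepdims=True)
        if np.any(row_sums == 0):
            empty = [self.categories[i] for i in
                     np.flatnonzero(self.counts.sum(axis=1) == 0)]
            raise AnalysisError(f"empty category rows: {empty}")
        return self.counts / row_sums

    def p_r(self) -> np.ndarray:
        """Marginal response distribution from the pooled column totals."""
        return self.counts.sum(axis=0) / self.counts.sum()


def make_bin_edges(n_bins: int, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    if n_bins < 2:
        raise AnalysisError("n_bins must be >= 2")
    if not hi > lo:
        raise AnalysisError("range upper bound must exceed lower bound")
    return np.linspace(lo, hi, n_bins + 1)


def assign_bins(values: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Bin indices: each bin is left-closed/right-open except the last,
    which is closed at the upper edge. Out-of-range values are clipped
    (with a warning)."""
    edges = np.asarray(bin_edges, dtype=float)
    lo, hi = edges[0], edges[-1]
    values = np.asarray(values, dtype=float)
    if np.any(values < lo) or np.any(values > hi):
        warnings.warn("responses outside bin range were clipped", stacklevel=2)
        values = np.clip(values, lo, hi)
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def bin_responses(
    activations: ActivationMatrix,
    unit: int,
    n_bins: int = 10,
    range: tuple[float, float] = (0.0, 1.0),
    bin_edges: Sequence[float] | None = None,
) -> BinnedResponseTable:
    """Accumulate one unit's (category x bin) response-count table.

    Bins are equally spaced over ``range`` by default; explicit
    ``bin_edges`` override (e.g. the worked example's printed edges
    0 / 0.33 / 0.67 / 1).
    """
    edges = np.asarray(bin_edges, float) if bin_edges is not None else make_bin_edges(n_bins, *range)
    if len(edges) < 3:
        raise AnalysisError("n_bins must be >= 2")
    values = activations.responses[:, unit]
    idx = assign_bins(values, edges)
    cats = np.unique(activations.labels)
    counts = np.zeros((len(cats), len(edges) - 1))
    for i, c in enumerate(cats):
        counts[i] = np.bincount(idx[activations.labels == c], minlength=len(edges) - 1)
    return BinnedResponseTable(counts=counts, bin_edges=edges, unit_id=unit,
                               categories=list(cats))


def single_cell_information(table: BinnedResponseTable, s) -> float:
    """Stimulus-specific information (bits) the unit carries about
    category ``s``; see the module docstring for the definition."""
    cats = list(table.categories)
    if s not in cats:
        raise AnalysisError(f"category {s!r} not in table")
    row = table.p_r_given_s()[cats.index(s)]
    marginal = table.p_r()
    nz = row > 0
    return float((row[nz] * np.log2(row[nz] / marginal[nz])).sum())


@dataclass
class InfoTable:
    """Per-unit, per-category information in bits for one condition subset."""

    info: np.ndarray
    n_bins: int
    condition: str = "all"
    unit_ids: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.info.ndim != 2:
            raise AnalysisError("info must be 2-D (units x categories)")
        if not list(self.unit_ids):
            self.unit_ids = list(range(self.info.shape[0]))

    @property
    def n_units(self) -> int:
        return self.info.shape[0]

    @property
    def n_categories(self) -> int:
        return self.info.shape[1]

    def max_per_unit(self) -> np.ndarray:
        return self.info.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        units, digits = np.meshgrid(self.unit_ids, np.arange(self.n_categories),
                                    indexing="ij")
        return pd.DataFrame({
            "unit": units.ravel(),
            "digit": digits.ravel(),
            "bits": self.info.ravel(),
            "condition": self.condition,
        })


def info_matrix(
    activations: ActivationMatrix,
    n_bins: int = 10,
    condition_filter: str = "all",
    range: tuple[float, float] = (0.0, 1.0),
) -> InfoTable:
    """Per-unit x per-category information on a condition subset.

    Applies :func:`bin_responses` + :func:`single_cell_information` to
    every (unit, category) on the filtered rows; binning uses the fixed
    global range (the sigmoid output interval by default), not per-unit
    ranges.
    """
    if condition_filter not in ("all", "both", "visual_only", "audio_only"):
        raise AnalysisError(f"unknown condition filter {condition_filter!r}")
    acts = activations.filtered(condition_filter)
    edges = make_bin_edges(n_bins, *range)
    idx = assign_bins(acts.responses, edges)
    cats = np.unique(acts.labels)
    n_units = acts.n_units
    info = np.empty((n_units, len(cats)))
    cat_index = np.searchsorted(cats, acts.labels)
    n_total = len(acts.labels)
    class_counts = np.bincount(cat_index, minlength=len(cats)).astype(float)
    for u in np.arange(n_units):
        flat = cat_index * n_bins + idx[:, u]
        counts = np.bincount(flat, minlength=len(cats) * n_bins).reshape(len(cats), n_bins)
        p_rs = counts / class_counts[:, None]
        p_r = counts.sum(axis=0) / n_total
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(counts > 0, p_rs * np.log2(p_rs / np.where(p_r > 0, p_r, 1.0)), 0.0)
        info[u] = terms.sum(axis=1)
    return InfoTable(info=info, n_bins=n_bins, condition=condition_filter)


def max_information(n_cat: int) -> float:
    """Upper bound on single-cell information with equal priors: log2(nCat)."""
    if n_cat < 1:
        raise AnalysisError("n_cat must be >= 1")
    return float(np.log2(n_cat))


def rank_order_curve(info: InfoTable) -> np.ndarray:
    """Per-unit maxima over categories, sorted descending (the curve
    plotted against unit rank)."""
    if info.n_units == 0:
        raise AnalysisError("empty info table")
    return np.sort(info.max_per_unit())[::-1]


def shuffled_info_null(
    activations: ActivationMatrix,
    n_bins: int = 10,
    condition_filter: str = "all",
    n_shuffles: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Label-permutation null distribution of per-unit maximum info.

    Returns an (n_shuffles, n_units) array of per-unit maxima computed
    after shuffling the sample labels; its upper percentiles bound the
    finite-sampling bias of the plug-in estimator.
    """
    acts = activations.filtered(condition_filter)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 31)))
    out = np.empty((n_shuffles, acts.n_units))
    for k in range(n_shuffles):
        shuffled = ActivationMatrix(acts.responses,
                                    rng.permutation(acts.labels),
                                    acts.conditions)
        out[k] = info_matrix(shuffled, n_bins=n_bins).max_per_unit()
    return out
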