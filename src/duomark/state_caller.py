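"""Four-state chromatin classification and pull-down recovery statistics.

From two single-mark tracks (H3K9me3 and H3K36me2/3 evidence) every genomic
bin is assigned one of four states — neither, K36-only, K9-only, bivalent —
by thresholding each track and combining the presence calls.  Against such a
state map, a pull-down track is summarized two ways:

composition
    the state distribution restricted to pull-down-positive bins (what an
    AND-logic reagent precipitates should be dominated by the bivalent
    state even though it covers a minority of the genome);
recovery
    per state, the fraction of that state's bins that are pull-down
    positive (the bivalent state should be recovered far more efficiently
    than single-mark states by an AND-logic reagent, and indistinguishably
    from K9-only by a K36-pocket-dead mutant).

Exact presence cutoffs are an analysis choice; two logged presets are
provided (genome mean + 1 SD of nonzero bins, and a stringent +2 SD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_quant import BinnedSignal, BinSet

logger = logging.getLogger("duomark")

__all__ = [
    "ThresholdSpec",
    "StateVector",
    "StateSummary",
    "STATE_NEITHER",
    "STATE_K36_ONLY",
    "STATE_K9_ONLY",
    "STATE_BIVALENT",
    "STATE_LABELS",
    "call_presence",
    "interior_mask",
    "classify_states",
    "pulldown_summary",
    "mean_signal_by_state",
]

STATE_NEITHER, STATE_K36_ONLY, STATE_K9_ONLY, STATE_BIVALENT = 0, 1, 2, 3
STATE_LABELS = ("neither", "k36_only", "k9_only", "bivalent")


@dataclass(frozen=True)
class ThresholdSpec:
    """Resolvable presence cutoff for one normalized track.

    method 'fixed'          -> cutoff = param (signal units)
    method 'mean_sd'        -> genome mean + param * SD over nonzero,
                               non-truncated bins (distribution-referenced:
                               suited to pull-down positivity, where only the
                               strongest enrichment should count)
    method 'median_mad'     -> genome median + param * 1.4826 * MAD
                               (background-referenced: suited to mark
                               presence, where anything clearly above the
                               unmarked background counts; assumes marked
                               bins are a minority so the median sits in the
                               background component)
    method 'top_percentile' -> the (100 - param)th percentile, i.e. the top
                               param percent of bins are positive
    """

    method: str = "mean_sd"
    param: float = 1.0
    label: str = "default"

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "mean_sd", "median_mad",
                               "top_percentile"):
            raise ValueError(f"unknown threshold method {self.method!r}")

    def resolve(self, signal: BinnedSignal) -> float:
        values = signal.norm
        if self.method == "fixed":
            return float(self.param)
        usable = values[~signal.bins.truncated]
        usable = usable[usable > 0]
        if len(usable) == 0:
            raise ValueError(
                f"threshold {self.label!r}: no nonzero bins to estimate from")
        if self.method == "mean_sd":
            return float(usable.mean() + self.param * usable.std(ddof=0))
        if self.method == "median_mad":
            med = float(np.median(usable))
            mad = float(np.median(np.abs(usable - med)))
            return med + self.param * 1.4826 * mad
        if np.all(usable == usable[0]):
            raise ValueError(
                f"threshold {self.label!r}: all-equal signal, percentile "
                "cutoff undefined")
        return float(np.percentile(usable, 100.0 - self.param))


DEFAULT = ThresholdSpec("mean_sd", 1.0, "default")
STRINGENT = ThresholdSpec("mean_sd", 2.0, "stringent")
# presence of a mark for state definition: anything clearly above the
# unmarked background, robust to the mark's density (a half-density dual
# region under the mixture hypothesis must still be called present --
# otherwise single-mark maps would trivially "distinguish" the hypotheses)
MARK_PRESENCE = ThresholdSpec("median_mad", 5.0, "mark-presence")


@dataclass
class StateVector:
    """Per-bin chromatin state over a BinSet, with the thresholds used."""

    bins: BinSet
    states: np.ndarray            # int8 codes (STATE_* constants)
    k9_cutoff: float | None = None
    k36_cutoff: float | None = None

    def __post_init__(self) -> None:
        if len(self.states) != self.bins.n_bins:
            raise ValueError("state vector length does not match the bin set")

    def mask(self, state: int) -> np.ndarray:
        return self.states == state

    def counts(self) -> dict[str, int]:
        return {STATE_LABELS[s]: int((self.states == s).sum())
                for s in range(4)}

    def fractions(self) -> dict[str, float]:
        n = len(self.states)
        return {k: v / n for k, v in self.counts().items()}

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.to_dataframe()
        df["state"] = [STATE_LABELS[s] for s in self.states]
        return df


@dataclass
class StateSummary:
    """Per-state counts plus pull-down composition and recovery.

    composition sums to 1 over states (None when the pull-down called no
    positive bin); recovery values are fractions in [0, 1].
    """

    state_counts: dict[str, int]
    genome_fractions: dict[str, float]
    composition: dict[str, float] | None
    recovery: dict[str, float]
    n_positive: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in STATE_LABELS:
            rows.append({
                "state": s,
                "n_bins": self.state_counts[s],
                "genome_fraction": self.genome_fractions[s],
                "composition": (np.nan if self.composition is None
                                else self.composition[s]),
                "recovery": self.recovery.get(s, np.nan),
            })
        return pd.DataFrame(rows)


def interior_mask(states: "StateVector") -> np.ndarray:
    """Bins whose chromosome neighbors share their state.

    Bins straddling a region boundary mix two states and carry intermediate
    signal; comparisons of per-state mean signal or recovery are computed on
    interior bins to avoid this binning artifact.  First/last bins of a
    chromosome count as interior on their missing side.
    """
    s = states.states
    ok = np.ones(len(s), dtype=bool)
    for chrom, (first, n) in states.bins.offsets.items():
        block = s[first:first + n]
        left_ok = np.ones(n, dtype=bool)
        right_ok = np.ones(n, dtype=bool)
        left_ok[1:] = block[1:] == block[:-1]
        right_ok[:-1] = block[:-1] == block[1:]
        ok[first:first + n] = left_ok & right_ok
    return ok


def call_presence(signal: BinnedSignal,
                  spec: ThresholdSpec = DEFAULT) -> np.ndarray:
    """Boolean per-bin presence: normalized value strictly above the resolved
    cutoff.  The cutoff is logged so downstream state maps are auditable."""
    cutoff = spec.resolve(signal)
    logger.info("presence cutoff for %s (%s): %.4g",
                signal.label, spec.label, cutoff)
    return signal.norm > cutoff


def classify_states(k9: np.ndarray, k36: np.ndarray, bins: BinSet,
                    k9_cutoff: float | None = None,
                    k36_cutoff: float | None = None) -> StateVector:
    """Combine two presence vectors into the four-state map:
    (F,F) neither, (F,T) K36-only, (T,F) K9-only, (T,T) bivalent."""
    k9 = np.asarray(k9, dtype=bool)
    k36 = np.asarray(k36, dtype=bool)
    if len(k9) != len(k36):
        raise ValueError("presence vectors differ in length")
    if len(k9) != bins.n_bins:
        raise ValueError("presence vectors do not match the bin set")
    states = np.zeros(len(k9), dtype=np.int8)
    states[~k9 & k36] = STATE_K36_ONLY
    states[k9 & ~k36] = STATE_K9_ONLY
    states[k9 & k36] = STATE_BIVALENT
    return StateVector(bins, states, k9_cutoff, k36_cutoff)


def pulldown_summary(states: StateVector,
                     pulldown_presence: np.ndarray) -> StateSummary:
    """Composition and per-state recovery of a pull-down against a state map."""
    pos = np.asarray(pulldown_presence, dtype=bool)
    if len(pos) != states.bins.n_bins:
        raise ValueError("pull-down vector does not match the bin set")
    counts = states.counts()
    fractions = states.fractions()
    n_pos = int(pos.sum())
    composition: dict[str, float] | None
    if n_pos == 0:
        composition = None
        logger.warning("pulldown_summary: no pull-down-positive bins; "
                       "composition undefined")
    else:
        composition = {STATE_LABELS[s]: float((pos & (states.states == s)).sum()) / n_pos
                       for s in range(4)}
    recovery = {}
    for s in range(4):
        label = STATE_LABELS[s]
        n_state = counts[label]
        if n_state == 0:
            continue
        recovery[label] = float((pos & (states.states == s)).sum()) / n_state
    return StateSummary(counts, fractions, composition, recovery, n_pos)


def mean_signal_by_state(signal: BinnedSignal,
                         region_sets: dict[str, np.ndarray]) -> dict[str, float]:
    """Mean normalized signal per bin set, with the genome-wide average
    subtracted (delta values; empty sets come back as NaN)."""
    genome_mean = float(signal.norm.mean())
    out = {}
    for label, mask in region_sets.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            out[label] = float("nan")
        else:
            out[label] = float(signal.norm[mask].mean()) - genome_mean
    return out
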