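"""Coexistence-vs-mixture inference for dual-positive chromatin regions.

Dual-positive (bivalent-state) bins can arise from true per-nucleosome
coexistence of both marks or from a mixture — different alleles, cells or
adjacent nucleosomes each carrying a single mark.  Two quantitative
signatures separate the hypotheses:

1. Signal-intensity ratio.  If a fraction phi of the marked molecules at a
   dual region carries a given mark (phi = 1 under coexistence, 1/2 under a
   symmetric mixture), the background-subtracted single-mark signal at dual
   regions is phi times the signal at pure single-mark regions.  The
   statistic reported here is

       r_m = (mean_m(bivalent bins) - mean_m(unmarked bins))
             / (mean_m(single-mark bins) - mean_m(unmarked bins))

   per mark m, whose expectation is exactly phi because read density is
   linear in the marked-molecule fraction.  (The display deltas of the
   underlying comparison subtract the genome-wide average instead; that
   statistic mixes the marked-region signal into its own baseline and does
   not converge to phi, so the verdict is based on the unmarked-baseline
   ratio.)  Uncertainty comes from a bin-level bootstrap — bins are the
   exchangeable unit of the comparison.

2. Sequential pull-down.  A two-step pull-down (first mark 1, then mark 2)
   retains only molecules carrying both marks, so its enrichment at dual
   regions over input collapses to background under a mixture and is strong
   under coexistence.

The verdict rule is this package's own formalization of the comparison (the
underlying experimental argument was made without a formal significance
procedure) and is reported as such, with configurable margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_quant import BinnedSignal
from .state_caller import (STATE_BIVALENT, STATE_K36_ONLY, STATE_K9_ONLY,
                           STATE_LABELS, STATE_NEITHER, StateVector,
                           interior_mask)

logger = logging.getLogger("duomark")

__all__ = [
    "CoexistenceReport",
    "coexistence_test",
    "mixture_expectation",
    "sequential_fold",
    "sequential_fold_bootstrap",
]

VERDICTS = ("coexistence-consistent", "mixture-consistent", "indeterminate")


@dataclass
class CoexistenceReport:
    """Per-mark delta statistics, ratios with bootstrap CIs, and the verdict."""

    delta: dict[str, dict[str, float]]       # mark -> region-set -> delta
    ratio: dict[str, float]                  # mark -> point estimate
    ratio_ci: dict[str, tuple[float, float]]  # mark -> bootstrap 95% CI
    ratio_se: dict[str, float]               # mark -> bootstrap SE
    verdict: str
    reason: str
    n_bootstrap: int
    epsilon: float
    delta_margin: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mark in self.ratio:
            lo, hi = self.ratio_ci[mark]
            rows.append({"mark": mark, "ratio": self.ratio[mark],
                         "ci_low": lo, "ci_high": hi,
                         "se": self.ratio_se[mark]})
        return pd.DataFrame(rows)

    def text_block(self) -> str:
        lines = [f"verdict: {self.verdict}", f"reason: {self.reason}",
                 "note: the verdict rule is this package's formalization of "
                 "the signal-ratio comparison, not a published procedure"]
        for mark in self.ratio:
            lo, hi = self.ratio_ci[mark]
            lines.append(f"  {mark}: ratio={self.ratio[mark]:.3f} "
                         f"95% CI [{lo:.3f}, {hi:.3f}] SE={self.ratio_se[mark]:.3f}")
        return "\n".join(lines)


def mixture_expectation(phi: float) -> float:
    """Expected background-subtracted signal ratio at dual regions when a
    fraction ``phi`` of molecules there carries the mark (densities equal
    elsewhere).  phi = 1 is the coexistence limit."""
    if not 0.0 < phi <= 1.0:
        raise ValueError(f"phi must be in (0, 1], got {phi}")
    return float(phi)


def _verdict(ci_low: dict[str, float], ci_high: dict[str, float],
             epsilon: float, delta_margin: float) -> tuple[str, str]:
    """Pure verdict rule over per-mark ratio CIs; monotone in the ratios."""
    coexist_bound = 1.0 - epsilon
    mixture_bound = 1.0 - delta_margin
    if all(lo >= coexist_bound for lo in ci_low.values()):
        return ("coexistence-consistent",
                f"both ratio CIs lie at or above {coexist_bound:.2f}")
    if all(hi < mixture_bound for hi in ci_high.values()):
        return ("mixture-consistent",
                f"both ratio CIs lie below {mixture_bound:.2f}")
    return ("indeterminate", "ratio CIs straddle the decision margins")


def coexistence_test(k9_signal: BinnedSignal, k36_signal: BinnedSignal,
                     states: StateVector, n_bootstrap: int = 1000,
                     seed: int = 0, epsilon: float = 0.05,
                     delta_margin: float = 0.25,
                     min_bins: int = 20,
                     interior_only: bool = True) -> CoexistenceReport:
    """Signal-ratio test of per-nucleosome coexistence at dual-positive bins.

    Verdict: coexistence-consistent when both marks' ratio bootstrap 95%
    intervals lie at or above 1 - epsilon; mixture-consistent when both lie
    below 1 - delta_margin; indeterminate otherwise (including degenerate
    inputs: too few bins per compared set, or zero net signal).

    With ``interior_only`` (default) the compared sets exclude bins at state
    boundaries, whose mixed content otherwise biases the set means.
    """
    if k9_signal.bins.n_bins != states.bins.n_bins:
        raise ValueError("signals and states must share a bin set")
    rng = np.random.default_rng([seed, 613])

    keep = interior_mask(states) if interior_only else \
        np.ones(states.bins.n_bins, dtype=bool)
    masks = {
        "bivalent": states.mask(STATE_BIVALENT) & keep,
        "k9_only": states.mask(STATE_K9_ONLY) & keep,
        "k36_only": states.mask(STATE_K36_ONLY) & keep,
        "neither": states.mask(STATE_NEITHER) & keep,
    }
    genome = np.ones(states.bins.n_bins, dtype=bool)
    delta = {}
    for mark, sig in (("k9", k9_signal), ("k36", k36_signal)):
        gm = float(sig.norm.mean())
        delta[mark] = {label: float(sig.norm[m].mean()) - gm if m.sum() else float("nan")
                       for label, m in masks.items()}
        delta[mark]["genome"] = 0.0

    def _empty_report(reason: str) -> CoexistenceReport:
        nan_ci = (float("nan"), float("nan"))
        return CoexistenceReport(
            delta, {"k9": float("nan"), "k36": float("nan")},
            {"k9": nan_ci, "k36": nan_ci},
            {"k9": float("nan"), "k36": float("nan")},
            "indeterminate", reason, n_bootstrap, epsilon, delta_margin)

    needed = {"k9": ("bivalent", "k9_only", "neither"),
              "k36": ("bivalent", "k36_only", "neither")}
    for mark, sets in needed.items():
        for label in sets:
            if int(masks[label].sum()) < min_bins:
                return _empty_report(
                    f"fewer than {min_bins} bins in the {label!r} set")

    idx = {label: np.flatnonzero(m) for label, m in masks.items()}
    values = {"k9": k9_signal.norm, "k36": k36_signal.norm}
    single = {"k9": "k9_only", "k36": "k36_only"}

    def _ratio(v: np.ndarray, biv: np.ndarray, pure: np.ndarray,
               base: np.ndarray) -> float:
        b0 = v[base].mean()
        num = v[biv].mean() - b0
        den = v[pure].mean() - b0
        if den <= 0:
            return float("nan")
        return float(num / den)

    ratio, ratio_ci, ratio_se = {}, {}, {}
    for mark in ("k9", "k36"):
        v = values[mark]
        biv, pure, base = idx["bivalent"], idx[single[mark]], idx["neither"]
        point = _ratio(v, biv, pure, base)
        if not np.isfinite(point):
            return _empty_report(
                f"no net {mark} signal above the unmarked baseline")
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            boots[b] = _ratio(v,
                              rng.choice(biv, size=len(biv)),
                              rng.choice(pure, size=len(pure)),
                              rng.choice(base, size=len(base)))
        boots = boots[np.isfinite(boots)]
        if len(boots) < max(10, n_bootstrap // 2):
            return _empty_report(f"bootstrap degenerate for mark {mark!r}")
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ratio[mark] = point
        ratio_ci[mark] = (float(lo), float(hi))
        ratio_se[mark] = float(boots.std(ddof=1))

    verdict, reason = _verdict({m: ci[0] for m, ci in ratio_ci.items()},
                               {m: ci[1] for m, ci in ratio_ci.items()},
                               epsilon, delta_margin)
    logger.info("coexistence_test: verdict=%s (k9 ratio %.3f, k36 ratio %.3f)",
                verdict, ratio["k9"], ratio["k36"])
    return CoexistenceReport(delta, ratio, ratio_ci, ratio_se, verdict,
                             reason, n_bootstrap, epsilon, delta_margin)


def sequential_fold(sequential_reads, input_reads,
                    states: StateVector) -> dict[str, float]:
    """Per-state fold enrichment of a sequential pull-down over input.

    fold(state) = library-normalized sequential read density in the state's
    bins divided by the equivalent input density (densities per covered
    base).  States with zero input density are reported as NaN.
    """
    from .signal_quant import count_reads  # local import avoids cycle at doc time

    bins = states.bins
    seq_counts = count_reads(sequential_reads, bins)
    inp_counts = count_reads(input_reads, bins)
    seq_total = seq_counts.sum()
    inp_total = inp_counts.sum()
    if seq_total == 0 or inp_total == 0:
        raise ValueError("sequential_fold: empty read set")
    lengths = bins.lengths().astype(float)
    out = {}
    for s in range(4):
        label = STATE_LABELS[s]
        mask = states.mask(s)
        bases = lengths[mask].sum()
        if bases == 0:
            out[label] = float("nan")
            continue
        seq_density = (seq_counts[mask].sum() / seq_total) / bases
        inp_density = (inp_counts[mask].sum() / inp_total) / bases
        out[label] = float(seq_density / inp_density) if inp_density > 0 else float("nan")
    return out


def sequential_fold_bootstrap(sequential_reads, input_reads,
                              states: StateVector, n_bootstrap: int = 200,
                              seed: int = 0) -> pd.DataFrame:
    """Per-state fold enrichment with a bin-level bootstrap SE.

    Reads of a sequential pull-down are heavily clustered (few molecules
    survive both captures, then are resequenced), so the effective sample
    size is far below the read count; resampling bins captures that
    clustering.  Returns a frame with fold, bootstrap SE and the bin count
    per state.
    """
    from .signal_quant import count_reads

    rng = np.random.default_rng([seed, 811])
    bins = states.bins
    seq_counts = count_reads(sequential_reads, bins)
    inp_counts = count_reads(input_reads, bins)
    seq_total, inp_total = seq_counts.sum(), inp_counts.sum()
    if seq_total == 0 or inp_total == 0:
        raise ValueError("sequential_fold_bootstrap: empty read set")
    rows = []
    for s in range(4):
        label = STATE_LABELS[s]
        idx = np.flatnonzero(states.mask(s))
        if len(idx) == 0:
            rows.append({"state": label, "fold": np.nan, "se": np.nan,
                         "n_bins": 0})
            continue

        def _fold(sel: np.ndarray) -> float:
            inp = inp_counts[sel].sum()
            if inp == 0:
                return np.nan
            return (seq_counts[sel].sum() / seq_total) / (inp / inp_total)

        fold = _fold(idx)
        boots = np.array([_fold(rng.choice(idx, size=len(idx)))
                          for _ in range(n_bootstrap)])
        boots = boots[np.isfinite(boots)]
        se = float(boots.std(ddof=1)) if len(boots) > 1 else np.nan
        rows.append({"state": label, "fold": fold, "se": se,
                     "n_bins": len(idx)})
    return pd.DataFrame(rows)
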