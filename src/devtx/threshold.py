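"""Background-calibrated expression threshold and per-stage expression calls.

The expressed/unexpressed RPKM boundary is estimated by contrasting the
late-stage gene RPKM distribution with the intergenic background: in
log2(RPKM + pseudocount) space a single Gaussian is fitted to the intergenic
sample and a two-component Gaussian mixture to the late-stage gene sample by
EM, with the lower component anchored to the background fit.  The threshold
is the maximum-likelihood classification boundary — the point between the
two component means where the weighted component densities are equal —
mapped back to the RPKM scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

DEFAULT_PSEUDOCOUNT = 1e-3


@dataclass
class ThresholdModel:
    """Fitted two-class model and the derived expression threshold."""

    threshold_rpkm: float
    threshold_log2: float
    background_mean: float
    background_sd: float
    background_weight: float
    expressed_mean: float
    expressed_sd: float
    log_likelihood: float
    pseudocount: float
    n_iterations: int

    def __post_init__(self) -> None:
        if self.threshold_rpkm <= 0:
            raise ValueError("threshold must be positive")
        if not self.background_mean < self.threshold_log2 < self.expressed_mean:
            raise ValueError("threshold must lie between the component means")


def _gauss_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi * sd**2) - (x - mean) ** 2 / (2 * sd**2)


def _equal_density_boundary(
    w1: float, m1: float, s1: float, w2: float, m2: float, s2: float
) -> float:
    """Point in (m1, m2) where the weighted component densities are equal."""

    def f(x: float) -> float:
        return (np.log(w1) + _gauss_logpdf(np.array([x]), m1, s1)[0]) - (
            np.log(w2) + _gauss_logpdf(np.array([x]), m2, s2)[0]
        )

    lo, hi = m1, m2
    if f(lo) <= 0 or f(hi) >= 0:
        raise ValueError(
            "no classification boundary between the component means; "
            "the two components are not separable"
        )
    return float(brentq(f, lo, hi, xtol=1e-12))


def estimate_threshold(
    gene_rpkm_late: Sequence[float],
    intergenic_rpkm: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    anchor_tol: float = 0.5,
    min_separation: float = 2.0,
) -> ThresholdModel:
    """Fit the two-class model and return the expression threshold.

    Parameters
    ----------
    gene_rpkm_late
        Pooled gene RPKM values from the late stages (a mixture of background
        and genuinely expressed genes).
    intergenic_rpkm
        Per-region intergenic RPKM values; fitted as a single background
        Gaussian in log2 space.
    pseudocount
        Added before log2 so zero RPKM stays finite.
    anchor_tol
        The background component's mean may move at most this many log2 units
        from the intergenic fit (its sd at most a factor 2) during EM.
    min_separation
        Minimum distance (log2 units) required between the fitted component
        means; fits with modes less than this far apart (default 2, i.e.
        4-fold) do not describe distinct expression classes and are rejected
        as having no separable second component.
    """
    genes = np.asarray(gene_rpkm_late, dtype=float)
    inter = np.asarray(intergenic_rpkm, dtype=float)
    if genes.size == 0 or inter.size == 0:
        raise ValueError("both the gene and the intergenic sample must be non-empty")
    if (genes < 0).any() or (inter < 0).any():
        raise ValueError("RPKM values must be non-negative")

    y = np.log2(genes + pseudocount)
    b = np.log2(inter + pseudocount)
    if np.ptp(y) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate sample: all values identical")

    bg_mean = float(b.mean())
    bg_sd = float(b.std(ddof=1))
    if bg_sd == 0:
        raise ValueError("degenerate intergenic sample: zero variance")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        m1, s1 = bg_mean, bg_sd
        upper = y[y > np.quantile(y, 0.5)]
        m2 = float(upper.mean()) + rng.normal(0, 0.25)
        s2 = max(float(upper.std(ddof=1)), 1e-3) * float(np.exp(rng.normal(0, 0.1)))
        w1 = float(np.clip(rng.normal(0.5, 0.1), 0.05, 0.95))
        ll_prev = -np.inf
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            # E step
            l1 = np.log(w1) + _gauss_logpdf(y, m1, s1)
            l2 = np.log(1 - w1) + _gauss_logpdf(y, m2, s2)
            m = np.maximum(l1, l2)
            log_norm = m + np.log(np.exp(l1 - m) + np.exp(l2 - m))
            r1 = np.exp(l1 - log_norm)
            ll = float(log_norm.sum())
            # M step with the background component tied to the intergenic fit
            n1 = r1.sum()
            n2 = len(y) - n1
            if n1 < 1e-8 or n2 < 1e-8:
                break
            w1 = float(np.clip(n1 / len(y), 1e-6, 1 - 1e-6))
            m1 = float(np.clip((r1 * y).sum() / n1, bg_mean - anchor_tol, bg_mean + anchor_tol))
            s1 = float(np.clip(np.sqrt((r1 * (y - m1) ** 2).sum() / n1), bg_sd / 2, bg_sd * 2))
            m2 = float(((1 - r1) * y).sum() / n2)
            s2 = float(max(np.sqrt(((1 - r1) * (y - m2) ** 2).sum() / n2), 1e-4))
            if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * (abs(ll_prev) + 1e-12):
                converged = True
                break
            ll_prev = ll
        if best is None or ll > best[0]:
            best = (ll, w1, m1, s1, m2, s2, n_iter, converged)

    ll, w1, m1, s1, m2, s2, n_iter, converged = best
    if m2 - m1 < min_separation:
        raise ValueError(
            f"no second component separable: fitted means {m1:.3f} and {m2:.3f} "
            f"are closer than {min_separation} log2 units"
        )
    if not converged:
        raise RuntimeError(
            f"EM did not converge after {max_iter} iterations "
            f"(best log-likelihood {ll:.6g}, means {m1:.3f}/{m2:.3f})"
        )
    x0 = _equal_density_boundary(w1, m1, s1, 1 - w1, m2, s2)
    threshold = float(2**x0 - pseudocount)
    return ThresholdModel(
        threshold_rpkm=threshold,
        threshold_log2=x0,
        background_mean=m1,
        background_sd=s1,
        background_weight=w1,
        expressed_mean=m2,
        expressed_sd=s2,
        log_likelihood=ll,
        pseudocount=pseudocount,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# expression calls and activation events


def call_expressed(rpkm_matrix: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Boolean gene x stage matrix: expressed iff RPKM strictly above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return rpkm_matrix > threshold


@dataclass
class ActivationEvents:
    """Genes switching expression state at each stage transition."""

    transitions: List[str]                      # "prev->current" labels
    activated: Dict[str, List[str]]             # transition -> gene ids
    inactivated: Dict[str, List[str]]

    def counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "activated": [len(self.activated[t]) for t in self.transitions],
                "inactivated": [len(self.inactivated[t]) for t in self.transitions],
            },
            index=self.transitions,
        )


def activation_events(calls: pd.DataFrame) -> ActivationEvents:
    """Activated = expressed now but not at the previous stage; and vice versa."""
    stages = list(calls.columns)
    if len(stages) < 2:
        raise ValueError("at least two stages are required")
    transitions, activated, inactivated = [], {}, {}
    for prev, curr in zip(stages, stages[1:]):
        label = f"{prev}->{curr}"
        transitions.append(label)
        now = calls[curr].to_numpy()
        before = calls[prev].to_numpy()
        activated[label] = list(calls.index[now & ~before])
        inactivated[label] = list(calls.index[~now & before])
    return ActivationEvents(transitions, activated, inactivated)


def activation_rates(
    event_counts: pd.DataFrame,
    stage_onset_hours: Mapping[str, float],
    stage_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genes activated/inactivated per minute at each stage transition."""
    if stage_order is None:
        stage_order = list(stage_onset_hours)
    times = [stage_onset_hours[s] for s in stage_order]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("stage onset times must be strictly increasing")
    minutes = {
        f"{a}->{b}": (stage_onset_hours[b] - stage_onset_hours[a]) * 60.0
        for a, b in zip(stage_order, stage_order[1:])
    }
    rates = event_counts.copy().astype(float)
    for label in rates.index:
        if label not in minutes:
            raise KeyError(f"transition {label!r} has no onset-time interval")
        rates.loc[label] = event_counts.loc[label] / minutes[label]
    return rates.rename(columns={"activated": "activated_per_min", "inactivated": "inactivated_per_min"})
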