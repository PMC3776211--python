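"""Propidium-iodide DNA-content histogram deconvolution.

A PI-stained cycling population shows a Gaussian G0/G1 peak at the diploid
DNA content ``mu``, a Gaussian G2/M peak near ``2 mu`` (position ratio
constrained to [1.85, 2.10]), and S-phase events spread between the two
peaks.  The classical broadened-rectangle (Dean-Jett-Fox-style) model is
used: S phase is a sum of narrow Gaussians on a grid from ``mu`` to
``r*mu`` with a common amplitude, and each peak's SD scales with its
position (constant CV).  Sub-G1 (apoptotic) events are gated
nonparametrically as everything below ``mu - k*sigma`` after the peak fit.

The model is fitted by nonlinear least squares with three deterministic
jittered restarts; fractions are component integrals renormalised to 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DNAHistogram", "PhaseFractions", "CellCycleModel", "fit_histogram",
           "estimate_non_dividing", "DEFAULT_REFERENCE_CYCLING_SG2M"]

#: Default S+G2/M occupancy of a fully cycling reference population, used by
#: the growth-fraction heuristic behind the non-dividing fraction.
DEFAULT_REFERENCE_CYCLING_SG2M = 0.35

#: Number of grid Gaussians used to broaden the S-phase rectangle.
_S_GRID = 24

#: Sub-G1 gate in G1-peak SDs below the G1 mode.
SUB_G1_K = 3.0


class FitError(RuntimeError):
    """Histogram fit failed; carries diagnostics in ``.diagnostics``."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class DNAHistogram:
    """Event counts over DNA-content channels (one culture)."""

    channel_midpoints: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        ch = np.asarray(self.channel_midpoints, dtype=float)
        ct = np.asarray(self.counts, dtype=float)
        if ch.shape != ct.shape or ch.ndim != 1:
            raise ValueError("channel_midpoints and counts must be equal-length 1-D")
        if np.any(np.diff(ch) <= 0):
            raise ValueError("channel midpoints must be strictly increasing")
        if np.any(ct < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "channel_midpoints", ch)
        object.__setattr__(self, "counts", ct)

    @property
    def n_events(self) -> int:
        return int(round(float(self.counts.sum())))


@dataclass(frozen=True)
class PhaseFractions:
    """Fitted phase fractions (sum to 1) plus fit diagnostics."""

    sub_g1: float
    g0g1: float
    s: float
    g2m: float
    non_dividing: float | None = None
    g1_mode: float | None = None
    g1_cv: float | None = None
    g2_g1_ratio: float | None = None
    residual_norm: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = (self.sub_g1, self.g0g1, self.s, self.g2m)
        if any(p < -1e-9 or p > 1 + 1e-9 for p in parts):
            raise ValueError(f"fractions outside [0,1]: {parts}")
        if abs(sum(parts) - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1, got {sum(parts)}")
        if self.g2_g1_ratio is not None and not (1.85 - 1e-9 <= self.g2_g1_ratio <= 2.10 + 1e-9):
            raise ValueError(f"G2/G1 position ratio {self.g2_g1_ratio} outside [1.85, 2.10]")


def _model_components(ch: np.ndarray, mu: float, sigma: float, r: float,
                      a1: float, a_s: float, a2: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel densities of the G1, S and G2/M components (unit areas x amps)."""
    g1 = a1 * np.exp(-0.5 * ((ch - mu) / sigma) ** 2)
    sigma2 = sigma * r  # constant-CV convention: SD scales with peak position
    g2 = a2 * np.exp(-0.5 * ((ch - r * mu) / sigma2) ** 2)
    grid = np.linspace(mu, r * mu, _S_GRID)
    s = np.zeros_like(ch)
    for g in grid:
        s += np.exp(-0.5 * ((ch - g) / sigma) ** 2)
    s *= a_s / _S_GRID
    return g1, s, g2


def _fit_once(ch, counts, p0, bounds):
    def resid(p):
        g1, s, g2 = _model_components(ch, *p)
        return (g1 + s + g2) - counts

    return least_squares(resid, p0, bounds=bounds, method="trf",
                         max_nfev=4000, xtol=1e-10, ftol=1e-10)


class CellCycleModel:
    """Deconvolution model for one DNA-content histogram.

    Parameters
    ----------
    hist : DNAHistogram
    min_events : int
        Fit refuses histograms with fewer events (default 500).
    """

    def __init__(self, hist: DNAHistogram, *, min_events: int = 500,
                 sub_g1_k: float = SUB_G1_K):
        if hist.channel_midpoints.size < 32:
            raise ValueError("need at least 32 channels to fit")
        if hist.n_events < min_events:
            raise FitError(f"too few events ({hist.n_events} < {min_events})")
        self.hist = hist
        self.sub_g1_k = sub_g1_k

    def fit(self) -> PhaseFractions:
        ch = self.hist.channel_midpoints
        counts = self.hist.counts
        total = counts.sum()

        # G1 seed: the global mode; G2 seed at twice that channel.
        mode_idx = int(np.argmax(counts))
        mu0 = float(ch[mode_idx])
        if counts[mode_idx] <= 0 or mu0 <= ch[0]:
            raise FitError("G1 peak not identifiable: no interior mode")
        # Width seed from channels within half-maximum of the mode.
        half = counts >= counts[mode_idx] / 2.0
        span = ch[half]
        sigma0 = max((span.max() - span.min()) / 2.355, (ch[1] - ch[0]))
        if np.count_nonzero(counts > 0) < 3:
            raise FitError("sigma not estimable: counts concentrated in <3 channels")

        bin_w = float(np.median(np.diff(ch)))
        a1_0 = float(counts[mode_idx])
        p0 = np.array([mu0, sigma0, 2.0, a1_0, 0.3 * a1_0, 0.3 * a1_0])
        lo = [mu0 * 0.7, bin_w * 0.25, 1.85, 0.0, 0.0, 0.0]
        hi = [mu0 * 1.3, mu0 * 0.5, 2.10, 5 * total, 5 * total, 5 * total]

        best = None
        rng = np.random.default_rng(20130301)  # deterministic jitter for restarts
        for k in range(3):
            p = p0 if k == 0 else p0 * rng.uniform(0.9, 1.1, size=p0.size)
            p = np.clip(p, lo, hi)
            try:
                sol = _fit_once(ch, counts, p, (lo, hi))
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise FitError("nonlinear fit diverged", {"mu0": mu0, "sigma0": sigma0})

        mu, sigma, r, a1, a_s, a2 = best.x
        # Sub-G1: observed mass below the gate mu - k*sigma.
        gate = mu - self.sub_g1_k * sigma
        sub_mass = float(counts[ch < gate].sum())
        f_low = sub_mass / total

        g1c, sc, g2c = _model_components(ch, mu, sigma, r, a1, a_s, a2)
        in_gate = ch >= gate
        areas = np.array([g1c[in_gate].sum(), sc[in_gate].sum(), g2c[in_gate].sum()])
        if areas.sum() <= 0:
            raise FitError("fit collapsed: zero component areas")
        cyc = (1.0 - f_low) * areas / areas.sum()
        parts = np.array([f_low, *cyc])
        parts = np.clip(parts, 0.0, None)
        parts /= parts.sum()

        return PhaseFractions(
            sub_g1=float(parts[0]), g0g1=float(parts[1]), s=float(parts[2]),
            g2m=float(parts[3]),
            g1_mode=float(mu), g1_cv=float(sigma / mu), g2_g1_ratio=float(r),
            residual_norm=float(np.sqrt(2 * best.cost) / total),
            diagnostics={"sub_g1_gate": float(gate), "converged": bool(best.success)},
        )


def fit_histogram(hist: DNAHistogram, **kwargs) -> PhaseFractions:
    """Convenience wrapper: ``CellCycleModel(hist, **kwargs).fit()``."""
    return CellCycleModel(hist, **kwargs).fit()


def estimate_non_dividing(fractions: PhaseFractions,
                          reference_cycling_sg2m: float = DEFAULT_REFERENCE_CYCLING_SG2M
                          ) -> float:
    """Non-dividing fraction via a growth-fraction heuristic.

    ``GF = min(1, (s + g2m) / reference)`` where ``reference`` is the S+G2/M
    occupancy of a fully cycling population; the non-dividing fraction is
    ``1 - GF``.  This is a stand-in definition (flagged in output metadata
    by callers) — there is no unique operational definition.
    """
    if not (0 < reference_cycling_sg2m <= 1):
        raise ValueError("reference_cycling_sg2m must be in (0, 1]")
    gf = min(1.0, (fractions.s + fractions.g2m) / reference_cycling_sg2m)
    return 1.0 - gf
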