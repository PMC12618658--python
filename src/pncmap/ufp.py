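"""Ultrafine-particle estimation via a Beta model of the sub-100 nm fraction.

Across station size distributions, the fraction of particle number below
100 nm is heavily left-massed: most sites are UFP-dominated. A two-parameter
Beta distribution fitted to those fractions summarizes that variability; its
mean converts any PNC field into a UFP field (UFP = fraction x PNC), and a
normal-approximation band (mean +/- 1.96 sd) expresses the spread. The band
is *not* a Beta quantile pair — its upper end may exceed 1 — so true Beta
quantiles are exposed alongside, clearly labelled.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_CLIP = 1e-6  # fractions are clipped into [CLIP, 1-CLIP] before the MLE


@dataclass(frozen=True)
class FractionModel:
    """Fitted Beta model of the sub-100 nm number fraction."""

    alpha: float
    beta: float
    mean_fraction: float
    sd: float
    band: tuple[float, float]  # mean +/- 1.96 sd (may exceed [0, 1])
    sample_mean: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if not 0.0 < self.mean_fraction < 1.0:
            raise ValueError("mean fraction must lie strictly inside (0, 1)")
        low, high = self.band
        if not low < self.mean_fraction < high:
            raise ValueError("band must bracket the mean fraction")

    def quantiles(self, q_low: float = 0.025, q_high: float = 0.975) -> tuple[float, float]:
        """True Beta quantiles — an alternative, support-respecting band."""
        return (
            float(stats.beta.ppf(q_low, self.alpha, self.beta)),
            float(stats.beta.ppf(q_high, self.alpha, self.beta)),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "alpha": self.alpha,
            "beta": self.beta,
            "mean_fraction": self.mean_fraction,
            "sd": self.sd,
            "band_low": self.band[0],
            "band_high": self.band[1],
            "beta_quantiles_95": list(self.quantiles()),
            "sample_mean": self.sample_mean,
            "n": self.n,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FractionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            alpha=d["alpha"],
            beta=d["beta"],
            mean_fraction=d["mean_fraction"],
            sd=d["sd"],
            band=(d["band_low"], d["band_high"]),
            sample_mean=d.get("sample_mean"),
            n=d.get("n"),
        )


def beta_summary(alpha: float, beta: float) -> tuple[float, float, tuple[float, float]]:
    """Closed-form mean, SD and mean +/- 1.96 sd band of Beta(alpha, beta)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("shape parameters must be positive")
    s = alpha + beta
    mean = alpha / s
    sd = math.sqrt(alpha * beta / (s * s * (s + 1.0)))
    return mean, sd, (mean - 1.96 * sd, mean + 1.96 * sd)


def fit_beta(fractions: Sequence[float], min_n: int = 30) -> FractionModel:
    """Maximum-likelihood Beta fit to fractions in (0, 1).

    Values are clipped into ``[1e-6, 1 - 1e-6]`` first (clip count logged);
    the support is fixed to [0, 1] so only the two shape parameters are
    estimated.
    """
    f = np.asarray(fractions, dtype=float)
    f = f[np.isfinite(f)]
    if f.size < min_n:
        raise ValueError(f"need at least {min_n} fractions, got {f.size}")
    n_clip = int(np.sum((f < _CLIP) | (f > 1.0 - _CLIP)))
    if n_clip:
        logger.info("clipped %d fraction(s) into [%g, %g]", n_clip, _CLIP, 1 - _CLIP)
    f = np.clip(f, _CLIP, 1.0 - _CLIP)
    if np.ptp(f) < 1e-12:
        raise ValueError("degenerate input: all fractions equal")
    a, b, _, _ = stats.beta.fit(f, floc=0.0, fscale=1.0)
    mean, sd, band = beta_summary(a, b)
    return FractionModel(
        alpha=float(a),
        beta=float(b),
        mean_fraction=mean,
        sd=sd,
        band=band,
        sample_mean=float(f.mean()),
        n=int(f.size),
    )


def estimate_ufp(pnc_field: np.ndarray, model: FractionModel) -> np.ndarray:
    """UFP field = fitted mean fraction times the PNC field, cellwise.

    Masked (NaN or ``numpy.ma``) cells stay masked; negative unmasked PNC
    is rejected.
    """
    pnc = np.ma.asarray(pnc_field) if isinstance(pnc_field, np.ma.MaskedArray) else np.asarray(
        pnc_field, dtype=float
    )
    valid = ~np.ma.getmaskarray(pnc) if isinstance(pnc, np.ma.MaskedArray) else np.isfinite(pnc)
    values = np.ma.getdata(pnc) if isinstance(pnc, np.ma.MaskedArray) else pnc
    if np.any(values[valid] < 0):
        raise ValueError("negative unmasked PNC values")
    return pnc * model.mean_fraction
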