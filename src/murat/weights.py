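"""MAF-based variant weighting for region tests.

Three schemes are supported, mirroring the common choices in set-based
rare-variant testing:

* ``identical`` — every variant gets weight 1 (W = I);
* ``beta:a1,a2`` — sqrt(w_j) is the Beta(a1, a2) density evaluated at the
  variant's MAF; the classic default Beta(1, 25) up-weights rare variants
  strongly (sqrt(w_j) = 25 (1 - MAF_j)^24);
* ``invsd`` — sqrt(w_j) = 1 / sqrt(MAF_j (1 - MAF_j)), the inverse of the
  binomial allele standard deviation.  This is the unnormalized form of the
  Beta(0.5, 0.5) density weighting (the two differ by the constant 1/pi,
  which cancels in the score test), so the scheme string ``beta:0.5,0.5``
  maps here.

Score-test p-values are invariant to positive rescaling of the whole weight
vector, so only the relative shape of w matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["WeightScheme", "compute_weights", "parse_scheme", "DEFAULT_SCHEMES"]


@dataclass(frozen=True)
class WeightScheme:
    kind: str  # "identical" | "beta" | "invsd"
    a1: float = float("nan")
    a2: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in ("identical", "beta", "invsd"):
            raise ValueError(f"unknown weight scheme kind {self.kind!r}")
        if self.kind == "beta" and not (self.a1 > 0 and self.a2 > 0):
            raise ValueError("beta weight scheme requires positive a1, a2")

    @property
    def name(self) -> str:
        if self.kind == "beta":
            return f"beta:{self.a1:g},{self.a2:g}"
        return self.kind

    def diverges_at_zero(self) -> bool:
        """True when the weight is unbounded as MAF -> 0."""
        return self.kind == "invsd" or (self.kind == "beta" and self.a1 < 1)


def parse_scheme(text: str) -> WeightScheme:
    """Parse a scheme string: ``identical``, ``invsd`` or ``beta:a1,a2``.

    ``beta:0.5,0.5`` is returned as the equivalent ``invsd`` scheme.
    """
    text = text.strip().lower()
    if text == "identical":
        return WeightScheme("identical")
    if text == "invsd":
        return WeightScheme("invsd")
    if text.startswith("beta:"):
        try:
            a1, a2 = (float(x) for x in text[5:].split(","))
        except ValueError as exc:
            raise ValueError(f"cannot parse beta parameters from {text!r}") from exc
        if a1 == 0.5 and a2 == 0.5:
            return WeightScheme("invsd")
        return WeightScheme("beta", a1, a2)
    raise ValueError(f"unknown weight scheme {text!r}")


#: the three weighting strategies compared in the BMD scan
DEFAULT_SCHEMES = (
    WeightScheme("identical"),
    WeightScheme("beta", 1.0, 25.0),
    WeightScheme("invsd"),
)


def compute_weights(mafs: np.ndarray, scheme: WeightScheme) -> np.ndarray:
    """Weight vector w (length v, nonnegative) for the given MAFs.

    MAFs must lie in (0, 0.5]; monomorphic variants (MAF = 0) must be
    dropped by the caller before weighting when the scheme diverges there.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs < 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in [0, 0.5]")
    if np.any(mafs == 0) and scheme.diverges_at_zero():
        raise ValueError(
            f"scheme {scheme.name} diverges at MAF=0: drop monomorphic "
            "variants before weighting"
        )
    if scheme.kind == "identical":
        return np.ones_like(mafs)
    if scheme.kind == "invsd":
        return 1.0 / (mafs * (1.0 - mafs))
    sqrt_w = stats.beta.pdf(mafs, scheme.a1, scheme.a2)
    return sqrt_w**2
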