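"""Stouffer Z-score combination of per-gene p-values across studies.

Each one-sided p-value is converted to a standard-normal quantile
z = Φ⁻¹(1 − p); the combined statistic is

    Z = Σ wᵢ zᵢ / sqrt(Σ wᵢ²)

and the combined p-value is the upper-tail probability 1 − Φ(Z), evaluated
through the log survival function so that values far below machine-epsilon
of 1 (down to ~1e-300) keep full relative precision.  Weights default to
equal; direction of effect is not aligned (inputs are p-values only), which
makes the combination anti-conservative if study effects disagree in sign —
acceptable for a screening/replication step where both studies are required
to support the same signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import log_ndtr, ndtri


@dataclass(frozen=True)
class MetaResult:
    gene_id: str
    trait: str
    p_values: tuple[float, ...]
    weights: tuple[float, ...]
    z_scores: tuple[float, ...]
    combined_z: float
    combined_p: float
    #: log10 of the combined p; stays finite even when combined_p itself
    #: underflows the double range (p below ~5e-324)
    combined_log10_p: float = float("nan")


def p_to_z(p: float) -> float:
    """Upper-tail standard-normal quantile z = Φ⁻¹(1 − p).

    Computed as −Φ⁻¹(p), which is exact in floating point for small p
    (whereas 1 − p would lose all precision below ~1e-17).
    """
    if not (0 < p < 1):
        raise ValueError(f"p must be in the open interval (0, 1), got {p}")
    return float(-ndtri(p))


def stouffer_combine(
    p_values: Sequence[float],
    weights: Sequence[float] | None = None,
    gene_id: str = "",
    trait: str = "",
) -> MetaResult:
    """Combine one-sided p-values across studies with Stouffer's method.

    With a single study the combined p equals the input p; equal weights
    are the default.
    """
    ps = [float(p) for p in p_values]
    if not ps:
        raise ValueError("at least one p-value is required")
    if weights is None:
        ws = [1.0] * len(ps)
    else:
        ws = [float(w) for w in weights]
        if len(ws) != len(ps):
            raise ValueError(
                f"{len(ps)} p-values but {len(ws)} weights"
            )
        if any(w <= 0 for w in ws):
            raise ValueError("weights must be positive")
    zs = [p_to_z(p) for p in ps]
    combined_z = float(
        np.dot(ws, zs) / np.sqrt(np.dot(ws, ws))
    )
    log_p = float(log_ndtr(-combined_z))
    return MetaResult(
        gene_id=gene_id,
        trait=trait,
        p_values=tuple(ps),
        weights=tuple(ws),
        z_scores=tuple(zs),
        combined_z=combined_z,
        combined_p=float(np.exp(log_p)),
        combined_log10_p=log_p / float(np.log(10.0)),
    )
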