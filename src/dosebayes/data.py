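"""Dose-response data container.

Responses live on a normalized inhibition scale where the dose-zero base
value is approximately ``B`` (100 in the DREAM convention) and a fully
effective drug drives the response towards 0. Replicates at the same dose
are distinct points.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseResponseDataset"]


@dataclass(frozen=True)
class DoseResponseDataset:
    """Immutable set of (dose-vector, response) measurements.

    Parameters
    ----------
    doses
        Array of shape ``(n, d)`` with ``d`` equal to 1 (monotherapy) or 2
        (combination). Monotherapy slices of a combination matrix are encoded
        with one zero dose.
    responses
        Array of shape ``(n,)`` on the normalized inhibition scale.
    B
        Normalized inhibition at dose zero (scale metadata), e.g. 100.
    drug_names
        Optional labels, one per dose dimension.
    strict
        When True (the default used by file loaders), require at least one
        strictly positive dose. Programmatic callers may relax this to build
        degenerate fixtures (e.g. a single dose-zero point).
    """

    doses: np.ndarray
    responses: np.ndarray
    B: float = 100.0
    drug_names: tuple[str, ...] | None = None
    strict: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        doses = np.atleast_2d(np.asarray(self.doses, dtype=float))
        if doses.shape[0] == 1 and doses.shape[1] > 2:
            doses = doses.T
        responses = np.asarray(self.responses, dtype=float).ravel()
        if doses.ndim != 2 or doses.shape[1] not in (1, 2):
            raise ValueError("doses must have shape (n, 1) or (n, 2)")
        if doses.shape[0] != responses.shape[0]:
            raise ValueError(
                f"{doses.shape[0]} dose vectors but {responses.shape[0]} responses"
            )
        if doses.shape[0] == 0:
            raise ValueError("dataset must contain at least one point")
        if not np.all(np.isfinite(doses)) or np.any(doses < 0):
            raise ValueError("doses must be finite and non-negative")
        if not np.all(np.isfinite(responses)):
            raise ValueError("responses must be finite")
        if not np.isfinite(self.B) or self.B <= 0:
            raise ValueError("B must be a positive finite scalar")
        if self.strict and not np.any(doses > 0):
            raise ValueError("at least one point must have a strictly positive dose")
        doses.setflags(write=False)
        responses.setflags(write=False)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "responses", responses)
        if doses.shape[1] == 2 and self.n_points < 4:
            warnings.warn(
                "very small combination dataset; posterior will be prior-dominated",
                stacklevel=2,
            )

    # -- basic geometry -----------------------------------------------------

    @property
    def n_points(self) -> int:
        return self.doses.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.doses.shape[1]

    @property
    def is_mono(self) -> bool:
        return self.n_drugs == 1

    @property
    def is_combo(self) -> bool:
        return self.n_drugs == 2

    def subset(self, indices) -> "DoseResponseDataset":
        idx = np.asarray(indices, dtype=int)
        return DoseResponseDataset(
            self.doses[idx],
            self.responses[idx],
            B=self.B,
            drug_names=self.drug_names,
            strict=False,
        )

    # -- layout masks for matrix-shaped data --------------------------------

    def base_mask(self) -> np.ndarray:
        """Points where every dose is zero."""
        return np.all(self.doses == 0, axis=1)

    def mono_slice_mask(self, drug: int) -> np.ndarray:
        """Points with a positive dose of ``drug`` (0-based) and zero of the other."""
        if not self.is_combo:
            raise ValueError("slice masks are defined for combination data only")
        other = 1 - drug
        return (self.doses[:, drug] > 0) & (self.doses[:, other] == 0)

    def grid_mask(self) -> np.ndarray:
        """Points where both doses are strictly positive."""
        if not self.is_combo:
            raise ValueError("grid mask is defined for combination data only")
        return np.all(self.doses > 0, axis=1)

    # -- fingerprint ---------------------------------------------------------

    def data_hash(self) -> str:
        """Stable fingerprint used to detect train/test contamination."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.doses).tobytes())
        h.update(np.ascontiguousarray(self.responses).tobytes())
        h.update(np.float64(self.B).tobytes())
        return h.hexdigest()

    # -- dose bounds used for the default IC50 prior -------------------------

    def dose_bounds(self) -> tuple[float, float]:
        """(delta, M): half the smallest non-zero dose and 10x the largest dose.

        Falls back to the wide uninformative defaults (1e-10, 1e6) when the
        dataset contains no positive dose.
        """
        positive = self.doses[self.doses > 0]
        if positive.size == 0:
            return 1e-10, 1e6
        return float(positive.min()) / 2.0, float(positive.max()) * 10.0
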