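"""External-parameter orthogonalization (EPO) of an interfering property.

When a dominant property (fat, through its scattering baseline) corrupts the
calibration of another (protein), the interferent's spectral subspace can be
estimated from a sample subset in which the *target* property is nearly
constant while the interferent spans its range.  The leading principal
directions of that subset's centred spectra span the interferent subspace;
projecting all spectra onto its orthogonal complement removes it before
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateDataError
from .io import SpectralBlock
from .multivariate import _fix_sign


@dataclass
class OrthogonalProjector:
    """Orthonormal basis V of the interferent subspace (wavelength space)."""

    basis: np.ndarray              # (p, k), orthonormal columns
    center: np.ndarray             # (p,) mean of the building subset
    n_components: int
    source_sample_ids: list[str]

    def __post_init__(self) -> None:
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ConfigurationError("projector basis is not orthonormal")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")


def build_projector(X_subset: np.ndarray, n_components: int = 2,
                    sample_ids: list[str] | None = None,
                    ) -> OrthogonalProjector:
    """Leading principal directions of a centred spectral subset.

    The subset should hold the target property nearly constant while the
    interferent spans its range, so its dominant variance *is* the
    interferent's signature.
    """
    X_subset = np.atleast_2d(np.asarray(X_subset, float))
    n, p = X_subset.shape
    if n < n_components + 1:
        raise ConfigurationError(
            f"subset of {n} samples cannot support {n_components} components")
    center = X_subset.mean(axis=0)
    Xc = X_subset - center
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # rank tolerance anchored on the raw data scale, so a subset of
    # (numerically almost) identical spectra is treated as rank 0
    scale = max(s[0] if s.size else 0.0, np.linalg.norm(X_subset))
    tol = max(n, p) * np.finfo(float).eps * scale
    rank = int(np.sum(s > tol))
    if rank < n_components:
        raise DegenerateDataError(
            f"subset rank {rank} below requested {n_components} components")
    V = vt[:n_components].T.copy()
    for k in range(n_components):
        V[:, k] *= _fix_sign(V[:, k])
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    return OrthogonalProjector(V, center, n_components, list(ids))


def apply_projector(projector: OrthogonalProjector, X) -> np.ndarray | SpectralBlock:
    """Project spectra onto the orthogonal complement of the basis.

    corrected = (X - center)(I - VV') + center.  Idempotent; spectra already
    orthogonal to V are unchanged.  Accepts a matrix or a SpectralBlock.
    """
    block = X if isinstance(X, SpectralBlock) else None
    M = np.atleast_2d(np.asarray(
        block.reflectance if block is not None else X, float))
    if M.shape[1] != projector.basis.shape[0]:
        raise ConfigurationError(
            f"grid mismatch: projector built on {projector.basis.shape[0]} "
            f"wavelengths, data has {M.shape[1]}")
    Xc = M - projector.center
    corrected = Xc - (Xc @ projector.basis) @ projector.basis.T + projector.center
    if block is not None:
        return block.with_reflectance(corrected)
    return corrected


def interferent_window_subset(composition: pd.DataFrame, target: str,
                              window: tuple[float, float]) -> np.ndarray:
    """Row indices whose *target* value lies inside the near-constant window.

    The default use holds protein in a narrow window (e.g. 3.1-3.3 g/100 mL)
    so the subset's spectral variation is driven by fat.
    """
    lo, hi = window
    if hi < lo:
        raise ConfigurationError("window upper bound below lower bound")
    values = composition[target].to_numpy(float)
    return np.flatnonzero((values >= lo) & (values <= hi))


def orthogonalize_block(block: SpectralBlock, composition: pd.DataFrame,
                        target: str = "protein",
                        window: tuple[float, float] = (3.1, 3.3),
                        n_components: int = 2,
                        ) -> tuple[SpectralBlock, OrthogonalProjector]:
    """Convenience: build the projector from the window subset and apply it."""
    rows = interferent_window_subset(composition, target, window)
    if rows.size < n_components + 1:
        raise DegenerateDataError(
            f"only {rows.size} samples have {target} in {window}; "
            f"need at least {n_components + 1}")
    ids = [block.sample_ids[i] for i in rows]
    projector = build_projector(block.reflectance[rows], n_components, ids)
    return apply_projector(projector, block), projector
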