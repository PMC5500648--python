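"""Subject-space distance matrices from module connectivity profiles.

For a fixed brain module i, a subject's *connectivity profile* is row i of
their SC matrix with the diagonal entry removed — the vector of streamline
counts from module i to each of the other M-1 modules.  The dissimilarity
between two subjects' profiles is the correlation chord distance

    d_uv = sqrt(2 * (1 - r_uv)),

where r_uv is the Pearson correlation between the two profiles.  d lies in
[0, 2]: identical shapes give 0, uncorrelated profiles sqrt(2), perfectly
anticorrelated profiles 2.  Because Pearson correlation is invariant to
positive affine rescaling, the distance responds to the *shape* of a
module's connectivity pattern, not its overall magnitude.

Computing d for every subject pair yields one N x N distance matrix per
module — the input to the distance-based group test in :mod:`.mdmr`.

The chord metric is Euclidean-embeddable (its Gower-centred matrix is
positive semidefinite), which guarantees a nonnegative between-group sum of
squares downstream.  ``metric="squared"`` keeps the squared chord 2*(1-r)
(range [0, 4]) for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, ValidationError
from .io import Cohort, ConnectivityMatrix

__all__ = [
    "ConnectivityProfile",
    "ModuleDistanceMatrix",
    "connectivity_profile",
    "pairwise_distance",
    "build_distance_matrix",
]

logger = logging.getLogger(__name__)

METRICS = ("chord", "squared")
ZERO_VARIANCE_POLICIES = ("error", "zero")
TRANSFORMS = (None, "log1p")


@dataclass(frozen=True)
class ConnectivityProfile:
    """Module-i row of one subject's SC matrix, diagonal excluded."""

    subject_id: str
    module: int  # 1-based
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class ModuleDistanceMatrix:
    """All pairwise profile distances for one module, in subject space."""

    module: int  # 1-based
    distances: np.ndarray
    correlations: np.ndarray
    subject_order: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return self.distances.shape[0]


def connectivity_profile(sc: ConnectivityMatrix, module: int) -> ConnectivityProfile:
    """Extract module ``module``'s (1-based) connectivity profile.

    Returns row ``module`` of the SC matrix with the (module, module) entry
    removed; remaining modules stay in ascending order, length M-1.
    """
    m = sc.n_modules
    if not 1 <= module <= m:
        raise InvalidParameterError(f"module index {module} outside [1, {m}]")
    row = sc.counts[module - 1]
    values = np.delete(row, module - 1)
    return ConnectivityProfile(subject_id=sc.subject_id, module=module, values=values)


def _as_vector(profile) -> np.ndarray:
    if isinstance(profile, ConnectivityProfile):
        return profile.values
    return np.asarray(profile, dtype=float)


def _pearson(x: np.ndarray, y: np.ndarray, zero_variance: str) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        if zero_variance == "error":
            raise ValidationError(
                "zero-variance connectivity profile: Pearson correlation undefined "
                "(pass zero_variance='zero' to define r = 0 for such pairs)"
            )
        logger.warning(
            "zero-variance profile encountered; defining r = 0 for this pair"
        )
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return min(1.0, max(-1.0, r))


def _distance_from_r(r, metric: str):
    if metric == "chord":
        return np.sqrt(np.clip(2.0 * (1.0 - r), 0.0, 4.0))
    if metric == "squared":
        return np.clip(2.0 * (1.0 - r), 0.0, 4.0)
    raise InvalidParameterError(f"unknown metric {metric!r}; choose from {METRICS}")


def pairwise_distance(
    profile_u,
    profile_v,
    metric: str = "chord",
    zero_variance: str = "error",
) -> float:
    """Correlation distance between two same-module connectivity profiles."""
    x, y = _as_vector(profile_u), _as_vector(profile_v)
    if (
        isinstance(profile_u, ConnectivityProfile)
        and isinstance(profile_v, ConnectivityProfile)
        and profile_u.module != profile_v.module
    ):
        raise ValidationError(
            f"profiles are for different modules ({profile_u.module} vs {profile_v.module})"
        )
    if x.shape != y.shape:
        raise ValidationError(f"profile length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError("profiles need length >= 3 for a meaningful correlation")
    if zero_variance not in ZERO_VARIANCE_POLICIES:
        raise InvalidParameterError(
            f"zero_variance must be one of {ZERO_VARIANCE_POLICIES}"
        )
    r = _pearson(x, y, zero_variance)
    return float(_distance_from_r(r, metric))


def build_distance_matrix(
    matrices: Sequence[ConnectivityMatrix],
    cohort: Cohort,
    module: int,
    metric: str = "chord",
    zero_variance: str = "error",
    transform: str | None = None,
) -> ModuleDistanceMatrix:
    """N x N distance matrix for one module over all cohort subjects.

    Subject order follows the cohort; every cohort subject must have exactly
    one SC matrix.  ``transform="log1p"`` applies log(1+x) to the counts
    before correlating (off by default: raw counts).
    """
    if transform not in TRANSFORMS:
        raise InvalidParameterError(f"transform must be one of {TRANSFORMS}")
    by_id = {sc.subject_id: sc for sc in matrices}
    missing = [sid for sid in cohort.subject_ids if sid not in by_id]
    if missing:
        raise ValidationError(f"no SC matrix for subject(s) {missing[:5]}")
    dims = {by_id[sid].n_modules for sid in cohort.subject_ids}
    if len(dims) > 1:
        raise ValidationError(f"inconsistent SC dimensions across subjects: {sorted(dims)}")

    profiles = np.stack(
        [connectivity_profile(by_id[sid], module).values for sid in cohort.subject_ids]
    )
    if transform == "log1p":
        profiles = np.log1p(profiles)

    stds = profiles.std(axis=1)
    degenerate = stds == 0.0
    if degenerate.any():
        if zero_variance == "error":
            bad = [cohort.subject_ids[i] for i in np.where(degenerate)[0]]
            raise ValidationError(
                f"zero-variance profile for subject(s) {bad[:5]} in module {module} "
                "(pass zero_variance='zero' to define r = 0 for such pairs)"
            )
        logger.warning(
            "module %d: %d zero-variance profile(s); r = 0 for affected pairs",
            module,
            int(degenerate.sum()),
        )
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    safe_norm = np.where(degenerate, 1.0, np.linalg.norm(centered, axis=1))
    unit = centered / safe_norm[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    if degenerate.any():
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)

    dist = _distance_from_r(corr, metric)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return ModuleDistanceMatrix(
        module=module,
        distances=dist,
        correlations=corr,
        subject_order=tuple(cohort.subject_ids),
    )
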