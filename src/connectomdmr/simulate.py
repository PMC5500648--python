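"""Synthetic structural-connectome cohorts with planted group effects.

The generator emulates a four-group case-control connectome study: each
subject carries an M x M symmetric matrix of nonnegative integer streamline
counts, groups share a common template of expected counts, and disease
effects are planted by multiplicatively attenuating a *subset* of a target
module's connections in the affected groups.  Attenuating only part of the
row matters: the downstream dissimilarity is based on Pearson correlation,
which is scale-invariant, so a uniform rescaling of a whole profile would
be invisible by construction — the planted effect must change the profile's
shape, mirroring the hypothesis that a subnetwork's connectivity *pattern*
is altered.

Model
-----
* Template: per-edge expected counts drawn once from a log-normal law
  (heavy-tailed across edges — a few strong bundles, many weak ones).
* Subject counts: negative-binomial around the (group-specific) expected
  counts with overdispersion ``alpha`` (variance mu + alpha * mu^2);
  ``alpha = 0`` falls back to Poisson.  Streamline counts are overdispersed
  nonnegative integers, which a Poisson law would understate.
* Effects: expected counts on edges {target} x {affected partners} are
  scaled by ``multiplier`` in the named groups; ``heterogeneity_sd`` adds
  per-subject, per-edge log-normal factors (mean 1) on those edges, so each
  affected subject deviates on their own set of connections — the
  within-group homogeneity contrast the analysis exploits.
* Demographics: ages are drawn from the same normal law for every group
  and sexes are assigned to the same female fraction per group, so groups
  are balanced by construction; no age or sex effect on connectivity is
  simulated.

Defaults mirror a 4 x 36 subject, 20-module design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .io import (
    AtlasPartition,
    Cohort,
    ConnectivityMatrix,
    write_atlas,
    write_cohort,
    write_sc_matrix,
)

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "Template",
    "make_template",
    "expected_counts",
    "generate_cohort",
    "severity_ladder",
    "ladder_effects",
    "default_partners",
    "write_dataset",
]

DEFAULT_GROUP_SIZES = {"Control": 36, "EMCI": 36, "LMCI": 36, "AD": 36}


@dataclass(frozen=True)
class CohortSpec:
    """Study design: parcellation size, group sizes, demographic laws."""

    n_modules: int = 20
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    mean_age: float = 75.0
    age_sd: float = 5.0
    sex_ratio: float = 0.5  # fraction female
    education_mean: float = 16.0
    education_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 2:
            raise InvalidParameterError("n_modules must be >= 2")
        sizes = dict(self.group_sizes)
        if not sizes:
            raise InvalidParameterError("at least one group required")
        bad = {g: n for g, n in sizes.items() if n < 2}
        if bad:
            raise InvalidParameterError(
                f"every group needs >= 2 subjects (within-group pairs): {bad}"
            )
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise InvalidParameterError("sex_ratio must lie in [0, 1]")
        if self.age_sd < 0 or self.education_sd < 0:
            raise InvalidParameterError("standard deviations must be nonnegative")
        object.__setattr__(self, "group_sizes", sizes)


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect on one module's connectivity profile."""

    target_module: int  # 1-based
    affected_partners: frozenset[int]
    multiplier: float
    applies_to_groups: frozenset[str]
    heterogeneity_sd: float = 0.0

    def __post_init__(self) -> None:
        partners = frozenset(int(p) for p in self.affected_partners)
        groups = frozenset(str(g) for g in self.applies_to_groups)
        if self.target_module in partners:
            raise InvalidParameterError(
                f"target module {self.target_module} cannot be its own partner"
            )
        if not partners:
            raise InvalidParameterError("affected_partners must be non-empty")
        if self.multiplier < 0:
            raise InvalidParameterError("multiplier must be >= 0")
        if self.heterogeneity_sd < 0:
            raise InvalidParameterError("heterogeneity_sd must be >= 0")
        object.__setattr__(self, "affected_partners", partners)
        object.__setattr__(self, "applies_to_groups", groups)


@dataclass(frozen=True)
class Template:
    """Shared expected-count matrix plus the count-noise overdispersion."""

    base_counts: np.ndarray
    dispersion: float = 0.1  # NB alpha: var = mu + alpha * mu^2; 0 => Poisson

    def __post_init__(self) -> None:
        base = np.asarray(self.base_counts, dtype=float)
        if base.ndim != 2 or base.shape[0] != base.shape[1]:
            raise InvalidParameterError("template must be a square matrix")
        if not np.allclose(base, base.T):
            raise InvalidParameterError("template must be symmetric")
        if np.any(base < 0):
            raise InvalidParameterError("template entries must be nonnegative")
        if self.dispersion < 0:
            raise InvalidParameterError("dispersion must be >= 0")
        object.__setattr__(self, "base_counts", base)

    @property
    def n_modules(self) -> int:
        return self.base_counts.shape[0]


def make_template(
    spec: CohortSpec,
    edge_mean: float = 50.0,
    seed: int | None = None,
    dispersion: float = 0.1,
    log_sigma: float = 0.5,
) -> Template:
    """Draw a symmetric template of expected streamline counts.

    Per-edge means are log-normal with overall mean ``edge_mean`` and
    log-scale spread ``log_sigma``, giving the heavy-tailed edge-weight
    distribution typical of streamline-count connectomes (a few dominant
    bundles, many near-zero connections).  Deterministic given ``seed``
    (defaults to ``spec.seed``).
    """
    if edge_mean <= 0:
        raise InvalidParameterError(f"edge_mean must be positive, got {edge_mean}")
    if log_sigma < 0:
        raise InvalidParameterError("log_sigma must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    m = spec.n_modules
    mu_log = np.log(edge_mean) - 0.5 * log_sigma**2  # mean of lognormal = edge_mean
    upper = rng.lognormal(mean=mu_log, sigma=log_sigma, size=(m, m))
    base = np.triu(upper)
    base = base + np.triu(base, 1).T
    return Template(base_counts=base, dispersion=dispersion)


def _check_effect_groups(spec: CohortSpec, effects: Sequence[EffectSpec]) -> None:
    known = set(spec.group_sizes)
    for eff in effects:
        unknown = eff.applies_to_groups - known
        if unknown:
            raise InvalidParameterError(
                f"effect on module {eff.target_module} names unknown group(s) "
                f"{sorted(unknown)}"
            )
        if not 1 <= eff.target_module <= spec.n_modules:
            raise InvalidParameterError(
                f"effect target module {eff.target_module} outside [1, {spec.n_modules}]"
            )
        out = {p for p in eff.affected_partners if not 1 <= p <= spec.n_modules}
        if out:
            raise InvalidParameterError(
                f"effect partners {sorted(out)} outside [1, {spec.n_modules}]"
            )


def expected_counts(
    template: Template, effects: Sequence[EffectSpec], group: str
) -> np.ndarray:
    """Expected count matrix for one group after applying its effects."""
    mu = template.base_counts.copy()
    for eff in effects:
        if group not in eff.applies_to_groups:
            continue
        t = eff.target_module - 1
        partners = np.array(sorted(eff.affected_partners)) - 1
        mu[t, partners] *= eff.multiplier
        mu[partners, t] = mu[t, partners]
    return mu


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Symmetric integer matrix: NB(mu, alpha) per upper-triangle edge."""
    m = mu.shape[0]
    iu = np.triu_indices(m)
    mu_flat = mu[iu]
    if alpha > 0:
        r = 1.0 / alpha
        p = r / (r + mu_flat)
        draws = rng.negative_binomial(r, p)
    else:
        draws = rng.poisson(mu_flat)
    counts = np.zeros((m, m), dtype=np.int64)
    counts[iu] = draws
    counts = counts + np.triu(counts, 1).T
    return counts


def generate_cohort(
    spec: CohortSpec,
    template: Template,
    effects: Sequence[EffectSpec] = (),
) -> tuple[Cohort, list[ConnectivityMatrix]]:
    """Generate a full cohort: metadata plus one SC matrix per subject.

    Deterministic given ``spec.seed``.  Subjects are ordered by group block
    in ``spec.group_sizes`` order; ids are ``<group>_<k>``.
    """
    if template.n_modules != spec.n_modules:
        raise InvalidParameterError(
            f"template has {template.n_modules} modules but spec requires {spec.n_modules}"
        )
    _check_effect_groups(spec, effects)
    rng = np.random.default_rng(spec.seed)

    records = []
    matrices: list[ConnectivityMatrix] = []
    for group, size in spec.group_sizes.items():
        mu_group = expected_counts(template, effects, group)
        het = [e for e in effects if group in e.applies_to_groups and e.heterogeneity_sd > 0]

        ages = np.round(rng.normal(spec.mean_age, spec.age_sd, size=size), 1)
        n_female = int(round(size * spec.sex_ratio))
        sexes = rng.permutation(np.array(["F"] * n_female + ["M"] * (size - n_female)))
        education = np.clip(
            np.round(rng.normal(spec.education_mean, spec.education_sd, size=size)),
            6,
            20,
        ).astype(int)

        for k in range(size):
            sid = f"{group}_{k + 1:03d}"
            mu = mu_group
            if het:
                mu = mu_group.copy()
                for eff in het:
                    # per-subject, per-edge log-normal factors (mean 1): each
                    # affected subject deviates on their own set of connections
                    t = eff.target_module - 1
                    partners = np.array(sorted(eff.affected_partners)) - 1
                    factors = rng.lognormal(
                        mean=-0.5 * eff.heterogeneity_sd**2,
                        sigma=eff.heterogeneity_sd,
                        size=partners.size,
                    )
                    mu[t, partners] *= factors
                    mu[partners, t] = mu[t, partners]
            counts = _sample_counts(rng, mu, template.dispersion)
            matrices.append(ConnectivityMatrix(subject_id=sid, counts=counts))
            records.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": ages[k],
                    "sex": sexes[k],
                    "education_years": education[k],
                }
            )
    return Cohort(pd.DataFrame(records)), matrices


def default_partners(module: int, n_modules: int) -> frozenset[int]:
    """Default affected-partner set: about half of the other modules.

    A proper subset of the target's row is required for the effect to alter
    the profile's shape (see module docstring); this takes the lower-indexed
    half of the remaining modules, deterministically.
    """
    others = [m for m in range(1, n_modules + 1) if m != module]
    return frozenset(others[: max(1, len(others) // 2)])


def ladder_effects(
    spec: CohortSpec,
    base_effect: EffectSpec,
    severity_multipliers: Sequence[float],
    extra_modules: Sequence[int] | None = None,
) -> list[EffectSpec]:
    """Effect list realising a severity ladder over the spec's groups.

    See :func:`severity_ladder` for the design; this exposes the planted
    effects so a combined (all-group) cohort can be generated with the same
    generative law as the stage-wise datasets.
    """
    groups = list(spec.group_sizes)
    if len(groups) < 2:
        raise InvalidParameterError("severity ladder needs a control plus >= 1 group")
    pathological = groups[1:]
    if len(severity_multipliers) != len(pathological):
        raise InvalidParameterError(
            f"{len(pathological)} pathological group(s) but "
            f"{len(severity_multipliers)} severity multipliers"
        )
    deviations = [abs(1.0 - m) for m in severity_multipliers]
    if any(b < a for a, b in zip(deviations, deviations[1:])):
        raise InvalidParameterError(
            "severity multipliers must deviate from 1 non-decreasingly across stages"
        )
    if extra_modules is None:
        extra_modules = [
            m for m in range(1, spec.n_modules + 1) if m != base_effect.target_module
        ][:2]
    if base_effect.target_module in extra_modules:
        raise InvalidParameterError("extra_modules cannot include the target module")

    # subject-level heterogeneity grows with severity: stages with a larger
    # deviation from multiplier 1 also get a proportionally larger share of
    # the base effect's heterogeneity_sd, so a multiplier-1 stage is an
    # exact null even when the base effect carries heterogeneity
    max_dev = max(deviations) or 1.0
    effects: list[EffectSpec] = []
    for group, mult, dev in zip(pathological, severity_multipliers, deviations):
        effects.append(
            replace(
                base_effect,
                multiplier=mult,
                heterogeneity_sd=base_effect.heterogeneity_sd * dev / max_dev,
                applies_to_groups=frozenset({group}),
            )
        )
    final_group, final_mult = pathological[-1], severity_multipliers[-1]
    for extra in extra_modules:
        effects.append(
            EffectSpec(
                target_module=extra,
                affected_partners=default_partners(extra, spec.n_modules),
                multiplier=final_mult,
                applies_to_groups=frozenset({final_group}),
                heterogeneity_sd=base_effect.heterogeneity_sd,
            )
        )
    return effects


def severity_ladder(
    spec: CohortSpec,
    template: Template,
    base_effect: EffectSpec,
    severity_multipliers: Sequence[float],
    extra_modules: Sequence[int] | None = None,
) -> dict[str, tuple[Cohort, list[ConnectivityMatrix]]]:
    """Stage-wise two-group datasets with a common control arm.

    The first group in ``spec.group_sizes`` is the control arm; each of the
    remaining (pathological) groups receives the base effect with its own
    multiplier, ordered so the deviation from 1 grows across stages.  The
    most severe group additionally receives the same-multiplier effect on
    ``extra_modules`` (default: the two lowest-indexed non-target modules),
    so late-stage alterations spread beyond the initial module.  Returns
    ``{"<control>_vs_<group>": (two-group Cohort, matrices)}`` in stage
    order; all stages share the identical control subjects.
    """
    groups = list(spec.group_sizes)
    control, pathological = groups[0], groups[1:]
    effects = ladder_effects(spec, base_effect, severity_multipliers, extra_modules)
    cohort, matrices = generate_cohort(spec, template, effects)
    by_id = {sc.subject_id: sc for sc in matrices}
    out: dict[str, tuple[Cohort, list[ConnectivityMatrix]]] = {}
    for group in pathological:
        sub = cohort.subset([control, group])
        out[f"{control}_vs_{group}"] = (
            sub,
            [by_id[sid] for sid in sub.subject_ids],
        )
    return out


def write_dataset(
    out_dir: str | Path,
    cohort: Cohort,
    matrices: Sequence[ConnectivityMatrix],
    provenance: Mapping | None = None,
) -> Path:
    """Write a dataset directory: cohort.tsv, atlas.tsv, sc/<id>.tsv.

    ``provenance`` (e.g. the generating spec and effects as plain dicts) is
    stored as provenance.json for reproducibility.
    """
    import json

    out = Path(out_dir)
    (out / "sc").mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out / "cohort.tsv")
    n_modules = matrices[0].n_modules
    write_atlas(AtlasPartition.default(n_modules), out / "atlas.tsv")
    for sc in matrices:
        write_sc_matrix(sc, out / "sc" / f"{sc.subject_id}.tsv")
    if provenance is not None:
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n"
        )
    return out
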