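"""Distance-based group comparison: pseudo-F, permutation p, FDR.

Given an N x N subject-space distance matrix D and a categorical group
label per subject, multivariate distance matrix regression (MDMR, also
known as PERMANOVA for a one-factor design) partitions the squared
distances into

    SS_T = (1/N) * sum_{u<v} d_uv^2
    SS_W = sum_g (1/n_g) * sum_{u<v in g} d_uv^2
    SS_B = SS_T - SS_W

and forms the pseudo-F statistic

    F = (SS_B / (m - 1)) / (SS_W / (N - m)),

with m groups of sizes n_g summing to N.  When D is the Euclidean distance
on univariate observations this reduces exactly to the classical one-way
ANOVA F.  For general dissimilarities the pseudo-F is not F-distributed
under the null, so the p-value comes from permuting the group labels:
shuffling labels is equivalent to jointly permuting rows and columns of D.

The default p-value convention is add-one, p = (1 + #{F_perm >= F_obs}) /
(1 + n_perm), which keeps p in (0, 1]; the literal convention
#{F_perm > F_obs} / n_perm is available via ``p_convention="literal"`` and
``tie_rule="gt"``.  Benjamini-Hochberg FDR adjustment across the M module
tests completes a connectome-wide scan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .distance import ModuleDistanceMatrix, build_distance_matrix
from .errors import InvalidParameterError, ValidationError
from .io import Cohort, ConnectivityMatrix

__all__ = [
    "GroupDesign",
    "MDMRResult",
    "total_ss",
    "within_ss",
    "pseudo_f",
    "permutation_test",
    "fdr_adjust",
    "run_mdmr",
    "rank_modules",
    "gower_center",
]

TIE_RULES = ("ge", "gt")
P_CONVENTIONS = ("add-one", "literal")


@dataclass(frozen=True)
class GroupDesign:
    """Per-subject group labels aligned with a distance matrix's subject order."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        sizes: dict[str, int] = {}
        for lab in labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        small = [g for g, n in sizes.items() if n < 2]
        if small:
            raise ValidationError(
                f"group(s) {small} have fewer than 2 subjects; within-group pairs required"
            )
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "GroupDesign":
        return cls(tuple(labels))

    @property
    def group_order(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return tuple(seen)

    @property
    def n_g(self) -> dict[str, int]:
        return {g: self.labels.count(g) for g in self.group_order}

    @property
    def m(self) -> int:
        return len(self.group_order)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def codes(self) -> np.ndarray:
        """Integer group codes in group_order, aligned with subjects."""
        index = {g: k for k, g in enumerate(self.group_order)}
        return np.array([index[lab] for lab in self.labels], dtype=np.int64)


@dataclass(frozen=True)
class MDMRResult:
    """Sum-of-squares decomposition and inference for one module."""

    module: int | None
    ss_total: float
    ss_within: float
    ss_between: float
    pseudo_f: float
    p_raw: float | None = None
    p_fdr: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    flags: tuple[str, ...] = ()


def _distances(dist) -> np.ndarray:
    """Accept a ModuleDistanceMatrix or a bare square distance array."""
    d = dist.distances if isinstance(dist, ModuleDistanceMatrix) else np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"distance matrix must be square, got shape {d.shape}")
    return d


def _check_alignment(d: np.ndarray, design: GroupDesign) -> None:
    if design.n != d.shape[0]:
        raise ValidationError(
            f"design has {design.n} labels but distance matrix is {d.shape[0]}x{d.shape[0]}"
        )


def total_ss(dist) -> float:
    """Total sum of squares: (1/N) * sum over unordered pairs of d^2."""
    d = _distances(dist)
    n = d.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 subjects for a total sum of squares")
    return float(np.sum(np.square(d)) / (2.0 * n))


def within_ss(dist, design: GroupDesign) -> float:
    """Within-group sum of squares: sum_g (1/n_g) sum_{u<v in g} d_uv^2."""
    d = _distances(dist)
    _check_alignment(d, design)
    d2 = np.square(d)
    codes = design.codes
    total = 0.0
    for g, size in enumerate(np.bincount(codes)):
        idx = np.where(codes == g)[0]
        total += float(np.sum(d2[np.ix_(idx, idx)])) / (2.0 * size)
    return total


def pseudo_f(dist, design: GroupDesign, module: int | None = None) -> MDMRResult:
    """Sum-of-squares decomposition and pseudo-F (no p-values yet).

    Degenerate inputs are flagged rather than erroring: SS_W = 0 with
    SS_B > 0 gives F = +inf (``perfect-separation``); SS_T = 0 gives
    F = nan (``degenerate``).
    """
    d = _distances(dist)
    _check_alignment(d, design)
    m, n = design.m, design.n
    if m < 2:
        raise InvalidParameterError("pseudo-F requires at least 2 groups")
    if n <= m:
        raise InvalidParameterError(
            f"need more subjects ({n}) than groups ({m}) for denominator df"
        )
    sst = total_ss(d)
    ssw = within_ss(d, design)
    ssb = sst - ssw
    flags: tuple[str, ...] = ()
    if sst == 0.0:
        f = float("nan")
        flags = ("degenerate",)
    elif ssw == 0.0:
        f = float("inf")
        flags = ("perfect-separation",)
    else:
        f = (ssb / (m - 1)) / (ssw / (n - m))
    return MDMRResult(
        module=module,
        ss_total=sst,
        ss_within=ssw,
        ss_between=ssb,
        pseudo_f=f,
        flags=flags,
    )


def _pseudo_f_batch(
    d2: np.ndarray, code_rows: np.ndarray, m: int, sst: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-F for many label vectors at once.

    ``code_rows`` is (n_perm, N) of integer group codes; group sizes are
    identical across rows (label permutations).  Returns (F, SS_W) per row.
    """
    n = d2.shape[0]
    ssw = np.zeros(code_rows.shape[0])
    for g in range(m):
        size = int(np.sum(code_rows[0] == g))
        ind = (code_rows == g).astype(float)
        ssw += np.einsum("pi,ij,pj->p", ind, d2, ind) / (2.0 * size)
    ssb = sst - ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (m - 1)) / (ssw / (n - m))
    f = np.where((ssw == 0.0) & (ssb > 0.0), np.inf, f)
    return f, ssw


def permutation_test(
    dist,
    design: GroupDesign,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence | None = 0,
    tie_rule: str = "ge",
    p_convention: str = "add-one",
    module: int | None = None,
) -> MDMRResult:
    """Permutation p-value for the pseudo-F by shuffling subject labels.

    The observed statistic is computed through the same vectorised code
    path as the permuted ones (row 0 of the permutation array), so a
    relabeling that maps every group onto itself reproduces F_obs exactly.
    """
    if n_perm < 1:
        raise InvalidParameterError(f"n_perm must be >= 1, got {n_perm}")
    if tie_rule not in TIE_RULES:
        raise InvalidParameterError(f"tie_rule must be one of {TIE_RULES}")
    if p_convention not in P_CONVENTIONS:
        raise InvalidParameterError(f"p_convention must be one of {P_CONVENTIONS}")
    d = _distances(dist)
    _check_alignment(d, design)
    observed = pseudo_f(d, design, module=module)

    rng = np.random.default_rng(seed)
    codes = design.codes
    rows = np.tile(codes, (n_perm + 1, 1))
    rows[1:] = rng.permuted(rows[1:], axis=1)
    f_all, _ = _pseudo_f_batch(np.square(d), rows, design.m, observed.ss_total)
    f_obs, f_perm = f_all[0], f_all[1:]

    if tie_rule == "ge":
        b = int(np.sum(f_perm >= f_obs))
    else:
        b = int(np.sum(f_perm > f_obs))
    if p_convention == "add-one":
        p_raw = (1.0 + b) / (1.0 + n_perm)
    else:
        p_raw = b / n_perm

    seed_int = None
    if isinstance(seed, (int, np.integer)):
        seed_int = int(seed)
    return replace(
        observed, p_raw=float(p_raw), n_permutations=int(n_perm), seed=seed_int
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidParameterError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise InvalidParameterError("all p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_mdmr(
    matrices: Sequence[ConnectivityMatrix],
    cohort: Cohort,
    design: GroupDesign | None = None,
    n_perm: int = 10_000,
    seed: int | Sequence[int] = 0,
    metric: str = "chord",
    zero_variance: str = "error",
    transform: str | None = None,
    tie_rule: str = "ge",
    p_convention: str = "add-one",
) -> list[MDMRResult]:
    """Connectome-wide scan: one MDMR test per module, FDR across modules.

    Per-module random streams are derived as SeedSequence([*seed, module])
    so any module can be recomputed independently and reproducibly.
    """
    if design is None:
        design = GroupDesign.from_labels(cohort.groups)
    if cohort.n_subjects != design.n:
        raise ValidationError("design and cohort sizes differ")
    by_id = {sc.subject_id: sc for sc in matrices}
    missing = [sid for sid in cohort.subject_ids if sid not in by_id]
    if missing:
        raise ValidationError(f"no SC matrix for subject(s) {missing[:5]}")
    n_modules = by_id[cohort.subject_ids[0]].n_modules

    seed_prefix = (int(seed),) if isinstance(seed, (int, np.integer)) else tuple(
        int(s) for s in seed
    )
    results = []
    for module in range(1, n_modules + 1):
        dist = build_distance_matrix(
            matrices,
            cohort,
            module,
            metric=metric,
            zero_variance=zero_variance,
            transform=transform,
        )
        ss = np.random.SeedSequence([*seed_prefix, module])
        res = permutation_test(
            dist,
            design,
            n_perm=n_perm,
            seed=ss,
            tie_rule=tie_rule,
            p_convention=p_convention,
            module=module,
        )
        results.append(replace(res, seed=seed_prefix[0]))
    adjusted = fdr_adjust([r.p_raw for r in results])
    return [replace(r, p_fdr=float(q)) for r, q in zip(results, adjusted)]


def rank_modules(results: Sequence[MDMRResult]) -> list[MDMRResult]:
    """Order modules by evidence strength.

    Primary key is the FDR-adjusted p-value; permutation p-values saturate
    at their resolution 1/(1+n_perm), so ties are broken by descending
    pseudo-F (larger F = stronger evidence), then by module index.
    """
    return sorted(
        results,
        key=lambda r: (
            r.p_fdr if r.p_fdr is not None else r.p_raw,
            -r.pseudo_f,
            r.module if r.module is not None else 0,
        ),
    )


def gower_center(dist) -> np.ndarray:
    """Gower-centred inner-product matrix G = -J (D^2 / 2) J, J = I - 11'/N.

    trace(G) equals SS_T, and summing per-group Gower traces of the group
    submatrices reproduces SS_W — the standard cross-check between the
    pairwise-sum and centred-matrix formulations.
    """
    d = _distances(dist)
    n = d.shape[0]
    a = -0.5 * np.square(d)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j
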