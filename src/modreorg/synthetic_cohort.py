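"""Synthetic multi-subject cohorts with planted modular covariance.

Subjects are stationary zero-mean Gaussian signals (no autocorrelation —
every downstream stage uses only zero-lag Pearson correlation, so temporal
structure would be invisible anyway). The planted region-correlation matrix
has ``rho_within`` inside planted modules, ``rho_between`` across them, and
a group-specific interhemispheric coupling ``rho_homotopic[group]`` on the
designated homotopic pair set: every left-right entry between members of
the affected set — mirrored pairs included — takes that value, so a low
coupling detaches the right half of the planted module the way the patient
group's network detaches it. Gray-matter concentration is drawn per subject
and region around group-shifted means for the affected regions.

One master seed spawns per-(group, subject) substreams, so adding subjects
or groups never reshuffles existing ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from modreorg.atlas_io import RegionAtlas, SubjectTimeSeries, default_atlas

logger = logging.getLogger("modreorg")

#: largest tolerated entrywise change from the PSD repair projection
MAX_PSD_ADJUSTMENT = 0.05


@dataclass
class CohortSpec:
    """Generative plan for a multi-group synthetic cohort.

    ``module_plan`` maps region id -> planted module label and must cover
    every atlas region exactly once. ``rho_homotopic`` maps group name ->
    interhemispheric coupling for the ``affected_pairs`` subset.
    ``gmc_means`` maps group name -> mean GMC of the affected regions;
    unaffected regions sit at ``gmc_baseline``.
    """

    atlas: RegionAtlas
    n_subjects: dict[str, int]
    T: int = 175
    module_plan: dict[int, int] = field(default_factory=dict)
    rho_within: float = 0.6
    rho_between: float = 0.1
    rho_homotopic: dict[str, float] = field(default_factory=dict)
    affected_pairs: str = "insula_module_pairs"
    gmc_baseline: float = 0.5
    gmc_means: dict[str, float] = field(default_factory=dict)
    gmc_sd: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 3:
            raise ValueError("T must be >= 3")
        for rho in (self.rho_within, self.rho_between,
                    *self.rho_homotopic.values()):
            if not abs(rho) < 1.0:
                raise ValueError(f"correlation target {rho} must satisfy "
                                 "0 <= |rho| < 1")
        if self.module_plan:
            planned = set(self.module_plan)
            regions = set(self.atlas.region_ids)
            if planned != regions:
                raise ValueError(
                    "module_plan must cover every region exactly once; "
                    f"missing {sorted(regions - planned)[:5]}, "
                    f"extra {sorted(planned - regions)[:5]}"
                )

    @property
    def groups(self) -> list[str]:
        return list(self.n_subjects)

    def planted_labels(self) -> np.ndarray:
        """Planted module label per region, in atlas order."""
        return np.array([self.module_plan[i] for i in self.atlas.region_ids],
                        dtype=int)


def default_module_plan(atlas: RegionAtlas,
                        affected_pairs: str = "insula_module_pairs",
                        n_other_modules: int = 3) -> dict[int, int]:
    """Four planted modules: the affected pair set is module 1, the
    remaining regions are cut into contiguous blocks that never separate a
    homotopic pair."""
    affected = set(atlas.named_subsets[affected_pairs])
    plan = {i: 1 for i in affected}
    rest: list[list[int]] = []
    seen: set[int] = set()
    for rid in atlas.region_ids:
        if rid in affected or rid in seen:
            continue
        partner = atlas.partners.get(rid)
        unit = [rid] if partner is None else [rid, partner]
        seen.update(unit)
        rest.append(unit)
    per = max(1, round(len(rest) / n_other_modules))
    for k, unit in enumerate(rest):
        label = min(k // per, n_other_modules - 1) + 2
        for rid in unit:
            plan[rid] = label
    return plan


def default_spec(n_per_group: int = 30, T: int = 175,
                 groups: tuple[str, ...] = ("CN", "AD"),
                 rho_homotopic: dict[str, float] | None = None,
                 gmc_means: dict[str, float] | None = None,
                 seed: int = 0, atlas: RegionAtlas | None = None,
                 **kwargs) -> CohortSpec:
    """The standard two-group (optionally three-group) cohort: four planted
    modules, strong within-module correlation, healthy interhemispheric
    coupling in CN and a weakened one in the patient groups."""
    atlas = atlas or default_atlas()
    if rho_homotopic is None:
        defaults = {"CN": 0.6, "MCI": 0.45, "AD": 0.15}
        rho_homotopic = {g: defaults.get(g, 0.6) for g in groups}
    if gmc_means is None:
        defaults = {"CN": 0.55, "MCI": 0.5, "AD": 0.45}
        gmc_means = {g: defaults.get(g, 0.5) for g in groups}
    return CohortSpec(
        atlas=atlas,
        n_subjects={g: n_per_group for g in groups},
        T=T,
        module_plan=default_module_plan(atlas),
        rho_homotopic=rho_homotopic,
        gmc_means=gmc_means,
        seed=seed,
        **kwargs,
    )


def build_target_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Unit-diagonal target correlation matrix for one group.

    If the plant is indefinite it is projected to the nearest positive
    semi-definite matrix (eigenvalue clipping at 0, re-normalized to unit
    diagonal); an adjustment larger than ``MAX_PSD_ADJUSTMENT`` on any entry
    is an error advising weaker contrasts.
    """
    atlas = spec.atlas
    n = atlas.n_regions
    labels = (spec.planted_labels() if spec.module_plan
              else np.ones(n, dtype=int))
    same = labels[:, None] == labels[None, :]
    c = np.where(same, spec.rho_within, spec.rho_between).astype(float)

    if group in spec.rho_homotopic:
        pairs = atlas.subset_pairs(spec.affected_pairs)
        left = [atlas.index_of(i) for i, _ in pairs]
        right = [atlas.index_of(j) for _, j in pairs]
        rho_h = spec.rho_homotopic[group]
        c[np.ix_(left, right)] = rho_h
        c[np.ix_(right, left)] = rho_h
    np.fill_diagonal(c, 1.0)

    eigval, eigvec = np.linalg.eigh(c)
    if eigval[0] < -1e-10:
        clipped = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
        d = np.sqrt(np.diag(clipped))
        repaired = clipped / np.outer(d, d)
        np.fill_diagonal(repaired, 1.0)
        adjustment = float(np.max(np.abs(repaired - c)))
        if adjustment > MAX_PSD_ADJUSTMENT:
            raise ValueError(
                f"correlation targets for group {group!r} are indefinite and "
                f"the PSD repair moves entries by {adjustment:.3f} "
                f"(> {MAX_PSD_ADJUSTMENT}); use weaker contrasts"
            )
        logger.warning("group %s: plant repaired to PSD "
                       "(max entry adjustment %.2e)", group, adjustment)
        c = repaired
    return c


def _subject_rng(seed: int, group_index: int, subject_index: int
                 ) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(group_index, subject_index))
    return np.random.default_rng(ss)


def simulate_cohort(spec: CohortSpec
                    ) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    """Draw every subject's time series and the per-subject GMC table.

    Returns ``(subjects, gmc)`` where ``gmc`` has columns ``subject_id``,
    ``group`` and one column per region id. Fully reproducible from
    ``spec.seed``; subjects are independent given the seed stream.
    """
    atlas = spec.atlas
    n = atlas.n_regions
    if spec.T < n:
        logger.warning("T=%d < N=%d regions: sample covariance is "
                       "rank-deficient (correlations still defined)",
                       spec.T, n)
    affected = set(atlas.named_subsets.get(spec.affected_pairs, ()))
    subjects: list[SubjectTimeSeries] = []
    gmc_rows = []
    for gi, group in enumerate(spec.groups):
        cov = build_target_covariance(spec, group)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        gmc_mu = np.full(n, spec.gmc_baseline)
        mean_affected = spec.gmc_means.get(group, spec.gmc_baseline)
        for k, rid in enumerate(atlas.region_ids):
            if rid in affected:
                gmc_mu[k] = mean_affected
        for si in range(spec.n_subjects[group]):
            rng = _subject_rng(spec.seed, gi, si)
            z = rng.standard_normal((spec.T, n))
            data = z @ chol.T
            if spec.noise_sd > 0:
                data = data + spec.noise_sd * rng.standard_normal((spec.T, n))
            sid = f"{group}_{si + 1:03d}"
            subjects.append(SubjectTimeSeries(subject_id=sid, group=group,
                                              data=data))
            gmc = rng.normal(gmc_mu, spec.gmc_sd)
            gmc_rows.append({"subject_id": sid, "group": group,
                             **{str(r): g for r, g
                                in zip(atlas.region_ids, gmc)}})
    return subjects, pd.DataFrame(gmc_rows)
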