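"""Synthetic expression and behavior data with plantable network structure.

The generator emulates the statistical layout the analysis assumes:
per-group multivariate-correlated regional densities (community structure,
designated hub regions with elevated cross-community correlation, and
group-specific edge strengthenings/weakenings) and group-structured
freezing-time samples with stated effect sizes. The generative family is a
multivariate normal truncated at 0 — the analysis models only second-order
structure (Pearson r), so matching the correlation target is what matters.
Modified targets that lose positive semi-definiteness are repaired by
eigenvalue clipping with a re-normalized unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import BehaviorTable, ExpressionMatrix, RegionCatalogue, default_catalogue

__all__ = [
    "EdgeModification",
    "GroupSpec",
    "SimScenario",
    "make_correlation_target",
    "simulate_expression",
    "simulate_behavior",
    "null_twin",
    "study_scenario",
    "EXP1_BEHAVIOR",
    "EXP3_BEHAVIOR",
]


@dataclass(frozen=True)
class EdgeModification:
    """Correlation delta on one region pair, or on a region's whole
    neighborhood when ``region_b`` is None (hub strengthening/weakening)."""

    region_a: str
    region_b: str | None
    delta: float


@dataclass(frozen=True)
class GroupSpec:
    """Per-group sampling parameters and structural modifications."""

    n_subjects: int
    mean_density: float = 1500.0
    density_sd: float = 300.0
    edge_modifications: tuple[EdgeModification, ...] = ()
    exclude_flagged: bool = False  # drop dorsal-hippocampal regions (lesioned group)

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError(
                "n_subjects must be >= 4 (downstream p-values are undefined)"
            )


@dataclass(frozen=True)
class SimScenario:
    """A full simulation scenario: region set, community structure, hub
    elevations, and per-group specifications."""

    communities: tuple[tuple[str, ...], ...]
    group_specs: Mapping[str, GroupSpec]
    base_corr_within: float = 0.7
    base_corr_between: float = 0.25
    hub_regions: tuple[str, ...] = ()
    hub_corr: float = 0.6
    rng_seed: int = 0
    catalogue: RegionCatalogue | None = None

    def __post_init__(self) -> None:
        regions = [r for comm in self.communities for r in comm]
        if len(set(regions)) != len(regions):
            raise ValueError("communities must partition the regions (no repeats)")
        unknown = set(self.hub_regions) - set(regions)
        if unknown:
            raise ValueError(f"hub regions not in any community: {sorted(unknown)}")
        for value in (self.base_corr_within, self.base_corr_between, self.hub_corr):
            if not (-1 < value < 1):
                raise ValueError("target correlations must lie in (-1, 1)")

    @property
    def regions(self) -> list[str]:
        return [r for comm in self.communities for r in comm]

    def group_regions(self, group: str) -> list[str]:
        spec = self.group_specs[group]
        if not spec.exclude_flagged:
            return self.regions
        if self.catalogue is None:
            raise ValueError("exclude_flagged requires a region catalogue")
        flagged = set(self.catalogue.flagged())
        return [r for r in self.regions if r not in flagged]


def _nearest_psd_correlation(c: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped PSD repair with re-normalized unit diagonal."""
    vals, vecs = np.linalg.eigh((c + c.T) / 2.0)
    if vals.min() >= 0:
        return c
    vals = np.clip(vals, 0.0, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def make_correlation_target(scenario: SimScenario, group: str) -> pd.DataFrame:
    """The group's region x region target correlation matrix.

    Block structure from the communities, hub rows elevated to ``hub_corr``,
    the group's edge modifications applied, then PSD-repaired.
    """
    regions = scenario.group_regions(group)
    index = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    c = np.full((n, n), scenario.base_corr_between)
    for comm in scenario.communities:
        members = [index[r] for r in comm if r in index]
        c[np.ix_(members, members)] = scenario.base_corr_within
    for hub in scenario.hub_regions:
        if hub not in index:
            continue
        i = index[hub]
        elevated = np.maximum(c[i], scenario.hub_corr)
        c[i, :] = elevated
        c[:, i] = elevated
    np.fill_diagonal(c, 1.0)
    for mod in scenario.group_specs[group].edge_modifications:
        if mod.region_a not in index:
            continue
        i = index[mod.region_a]
        if mod.region_b is None:
            c[i, :] += mod.delta
            c[:, i] += mod.delta
            c[i, i] = 1.0
        else:
            if mod.region_b not in index:
                continue
            j = index[mod.region_b]
            c[i, j] += mod.delta
            c[j, i] += mod.delta
    off = ~np.eye(n, dtype=bool)
    if (np.abs(c[off]) >= 1).any():
        raise ValueError("infeasible target: modified |r| >= 1")
    c = _nearest_psd_correlation(c)
    return pd.DataFrame(c, index=regions, columns=regions)


def simulate_expression(
    scenario: SimScenario, rng_seed: int | None = None
) -> dict[str, ExpressionMatrix]:
    """Draw each group's subjects x regions density matrix.

    Densities are multivariate normal with the group's target correlation,
    location ``mean_density`` and scale ``density_sd``, truncated at 0
    (negligible mass is removed when means sit >= 3 sd above zero). The same
    seed always yields the same matrices.
    """
    seed = scenario.rng_seed if rng_seed is None else rng_seed
    streams = np.random.SeedSequence(seed).spawn(len(scenario.group_specs))
    out: dict[str, ExpressionMatrix] = {}
    for (label, spec), stream in zip(scenario.group_specs.items(), streams):
        rng = np.random.default_rng(stream)
        target = make_correlation_target(scenario, label)
        regions = list(target.columns)
        vals, vecs = np.linalg.eigh(target.to_numpy())
        scale_matrix = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
        z = rng.standard_normal((spec.n_subjects, len(regions)))
        x = spec.mean_density + spec.density_sd * (z @ scale_matrix.T)
        x = np.clip(x, 0.0, None)
        subjects = [f"{label}_{i + 1:02d}" for i in range(spec.n_subjects)]
        out[label] = ExpressionMatrix(
            data=pd.DataFrame(x, index=subjects, columns=regions),
            groups=pd.Series(label, index=subjects),
            catalogue=scenario.catalogue,
        )
    return out


def simulate_behavior(
    group_means: Mapping[str, float],
    group_sds: Mapping[str, float],
    group_ns: Mapping[str, int],
    session_length_s: float = 300.0,
    rng_seed: int = 0,
) -> BehaviorTable:
    """Per-group freezing-time samples, truncated to [0, session length]."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for label in group_means:
        n = group_ns[label]
        draws = group_means[label] + group_sds[label] * rng.standard_normal(n)
        draws = np.clip(draws, 0.0, session_length_s)
        for i, value in enumerate(draws):
            rows.append(
                {
                    "subject": f"{label}_{i + 1:02d}",
                    "group": label,
                    "freezing_s": float(value),
                }
            )
    return BehaviorTable(pd.DataFrame(rows), session_length_s=session_length_s)


def null_twin(scenario: SimScenario) -> SimScenario:
    """The scenario with every group's edge modifications removed, so all
    groups share one correlation structure (type-I-error suites)."""
    specs = {
        label: replace(spec, edge_modifications=())
        for label, spec in scenario.group_specs.items()
    }
    return replace(scenario, group_specs=specs)


# functional communities of the default scenario: anatomical systems with the
# amygdala split into the basolateral complex and the central nuclei
_DEFAULT_COMMUNITIES = (
    ("LADL", "LAVL", "LAVM", "BLA", "BLP", "BLV"),
    ("CeC", "CeL", "CeM"),
    ("dCA1", "dCA3", "dDG"),
    ("vCA1", "vCA3", "vDG", "vSub"),
    ("Per_36", "Per_35", "Por", "DLE", "DIE", "MEnt"),
    ("PrL", "IL", "Cg1", "Cg2", "MO"),
    ("RSC", "RSGd", "RSGv"),
)


def study_scenario(
    rng_seed: int = 0,
    n_sham: int = 9,
    n_lesion: int = 10,
    catalogue: RegionCatalogue | None = None,
) -> SimScenario:
    """The default study-shaped scenario: 30 catalogued regions in anatomical
    communities, a control group (full region set) and a lesioned group
    missing the dorsal-hippocampal regions. IL is planted as the control
    hub (elevated cross-community correlation); the lesioned group's
    structure strengthens the RSC and Per_36 neighborhoods and weakens the
    IL neighborhood, planting the control-vs-lesion hub contrast. Hub
    elevations are sized so the planted hub's expected strength clears the
    strongest community regions by several times the sampling noise of a
    summed correlation row at the default group sizes."""
    cat = catalogue or default_catalogue()
    group_specs = {
        "SHAM": GroupSpec(n_subjects=n_sham),
        "dHPC": GroupSpec(
            n_subjects=n_lesion,
            exclude_flagged=True,
            edge_modifications=(
                EdgeModification("RSC", None, 0.3),
                EdgeModification("Per_36", None, 0.3),
                EdgeModification("IL", None, -0.35),
                # lesion-induced broad weakening of remaining interactions
                EdgeModification("vSub", None, -0.25),
                EdgeModification("vCA1", None, -0.25),
                EdgeModification("BLV", None, -0.25),
            ),
        ),
    }
    return SimScenario(
        communities=_DEFAULT_COMMUNITIES,
        group_specs=group_specs,
        base_corr_within=0.6,
        base_corr_between=0.25,
        hub_regions=("IL",),
        hub_corr=0.68,
        rng_seed=rng_seed,
        catalogue=cat,
    )


# Study-shaped behavioral defaults: group sizes as reported for the memory
# cohorts; means/sds chosen to reproduce the reported effect-size ordering
# (medium lesion effect, large shock-control effects) within a 300 s test.
EXP1_BEHAVIOR = {
    "group_means": {"SHAM": 150.0, "dHPC": 115.0, "Imm": 40.0},
    "group_sds": {"SHAM": 55.0, "dHPC": 55.0, "Imm": 30.0},
    "group_ns": {"SHAM": 12, "dHPC": 12, "Imm": 8},
    "session_length_s": 300.0,
}

EXP3_BEHAVIOR = {
    "group_means": {"SHAM": 190.0, "dHPC": 165.0, "RSC": 150.0, "dHPC-RSC": 110.0},
    "group_sds": {"SHAM": 55.0, "dHPC": 55.0, "RSC": 55.0, "dHPC-RSC": 55.0},
    "group_ns": {"SHAM": 10, "dHPC": 9, "RSC": 9, "dHPC-RSC": 11},
    "session_length_s": 300.0,
}
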