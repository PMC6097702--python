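"""Core domain types for co-activation network analysis.

The analysis works on cross-subject tables of regional marker density
(e.g. pCREB-positive nuclei per mm^2), behavioral freezing-time tables,
and a catalogue describing the brain regions under study.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_SYSTEMS = (
    "amygdalar",
    "dorsal-hippocampal",
    "ventral-hippocampal",
    "parahippocampal",
    "prefrontal",
    "retrosplenial",
)


@dataclass(frozen=True)
class RegionInfo:
    """One brain region: short key, full name, anatomical system, lesion flag."""

    abbreviation: str
    full_name: str
    system: str
    in_dorsal_hippocampus: bool = False


class RegionCatalogue:
    """Ordered, unique set of :class:`RegionInfo` with case-insensitive lookup."""

    def __init__(self, regions: Iterable[RegionInfo]):
        self.regions = list(regions)
        keys = [r.abbreviation for r in self.regions]
        if len(set(k.casefold() for k in keys)) != len(keys):
            raise ValueError("region abbreviations must be unique (case-insensitive)")
        self._by_folded = {r.abbreviation.casefold(): r for r in self.regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation.casefold() in self._by_folded

    @property
    def abbreviations(self) -> list[str]:
        return [r.abbreviation for r in self.regions]

    def lookup(self, name: str) -> RegionInfo:
        """Resolve a region name case-insensitively; raise with the offending label."""
        try:
            return self._by_folded[name.casefold()]
        except KeyError:
            raise KeyError(f"unknown region name: {name!r}") from None

    def subset(self, abbreviations: Sequence[str]) -> "RegionCatalogue":
        return RegionCatalogue(self.lookup(a) for a in abbreviations)

    def flagged(self) -> list[str]:
        return [r.abbreviation for r in self.regions if r.in_dorsal_hippocampus]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionCatalogue":
        required = {"abbreviation", "full_name", "system", "in_dorsal_hippocampus"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalogue missing columns: {sorted(missing)}")
        regions = []
        for row in df.itertuples(index=False):
            flag = row.in_dorsal_hippocampus
            if isinstance(flag, str):
                flag = flag.strip().casefold() in ("true", "1", "yes")
            regions.append(
                RegionInfo(
                    abbreviation=str(row.abbreviation),
                    full_name=str(row.full_name),
                    system=str(row.system),
                    in_dorsal_hippocampus=bool(flag),
                )
            )
        return cls(regions)


def default_catalogue() -> RegionCatalogue:
    """The packaged 30-region catalogue (3 regions flagged dorsal-hippocampal)."""
    ref = importlib.resources.files("coactnet.data").joinpath("region_catalogue.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh)
    return RegionCatalogue.from_frame(df)


@dataclass
class ExpressionMatrix:
    """Subjects x regions density table with one group label per subject.

    ``data`` is indexed by subject identifier with one column per region
    abbreviation; ``groups`` maps each subject to its group label. Densities
    must be finite, non-negative and complete (no missing cells): silent
    variation in n would corrupt downstream correlation p-values.
    """

    data: pd.DataFrame
    groups: pd.Series
    catalogue: RegionCatalogue | None = None

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if not self.data.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            bad = list(self.groups[self.groups.isna()].index)
            raise ValueError(f"subjects without group label: {bad}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate subject identifiers")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate region columns")
        if self.data.isna().any().any():
            cells = [
                (str(i), str(c))
                for i, c in zip(*np.where(self.data.isna().to_numpy()))
            ]
            raise ValueError(f"missing cells (no imputation performed): {cells[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("densities must be finite")
        if (values < 0).any():
            raise ValueError("densities must be >= 0")
        for label, count in self.groups.value_counts().items():
            if count < 4:
                raise ValueError(
                    f"group {label!r} has {count} subjects; at least 4 are required "
                    "for correlation p-values (n - 2 >= 2)"
                )

    @property
    def regions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def group_labels(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def for_group(self, label: str) -> "ExpressionMatrix":
        mask = self.groups == label
        if not mask.any():
            raise KeyError(f"no subjects in group {label!r}")
        return ExpressionMatrix(
            self.data.loc[mask], self.groups.loc[mask], self.catalogue
        )

    def restrict(self, regions: Sequence[str]) -> "ExpressionMatrix":
        missing = [r for r in regions if r not in self.data.columns]
        if missing:
            raise KeyError(f"regions not in matrix: {missing}")
        return ExpressionMatrix(self.data[list(regions)], self.groups, self.catalogue)


@dataclass
class BehaviorTable:
    """Per-subject total freezing time (seconds) with group labels."""

    df: pd.DataFrame  # columns: subject, group, freezing_s
    session_length_s: float | None = None

    def __post_init__(self) -> None:
        required = {"subject", "group", "freezing_s"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"behavior table missing columns: {sorted(missing)}")
        if len(self.df) == 0:
            raise ValueError("no rows")
        freezing = pd.to_numeric(self.df["freezing_s"], errors="coerce")
        if freezing.isna().any():
            raise ValueError("non-numeric freezing values")
        if (freezing < 0).any():
            raise ValueError("negative freezing values")
        if self.session_length_s is not None and (
            freezing > self.session_length_s
        ).any():
            raise ValueError("freezing exceeds session length")
        self.df = self.df.assign(freezing_s=freezing.astype(float)).reset_index(
            drop=True
        )

    def group_counts(self) -> dict[str, int]:
        return self.df["group"].value_counts().to_dict()

    def sample(self, group: str) -> np.ndarray:
        values = self.df.loc[self.df["group"] == group, "freezing_s"].to_numpy()
        if values.size == 0:
            raise KeyError(f"no subjects in group {group!r}")
        return values


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the full pipeline.

    thresholds: p-value levels applied to the correlation matrices, strictly
        decreasing, as in the three-level analysis (0.05, 0.025, 0.01).
    n_resamples: bootstrap / permutation / rewired-null ensemble size.
    hub_quantile: fraction of most-central regions intersected per metric.
    hub_min_metrics: metrics a region must rank highly in to be a hub.
    z_cutoff: |dC| above which an edge difference is called significant.
    """

    thresholds: tuple[float, ...] = (0.05, 0.025, 0.01)
    n_resamples: int = 10_000
    rng_seed: int = 0
    hub_quantile: float = 0.25
    hub_min_metrics: int = 3
    z_cutoff: float = 2.0

    def __post_init__(self) -> None:
        t = tuple(self.thresholds)
        if not t or any(not (0 < x < 1) for x in t):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(b >= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly decreasing")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not (0 < self.hub_quantile < 1):
            raise ValueError("hub_quantile must lie in (0, 1)")

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, rng_seed=seed)
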