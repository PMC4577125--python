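"""Core in-memory containers shared by all analysis stages.

The pipeline operates on sample-matched omics layers for a two-group
phenotype contrast (here labelled ``high`` vs ``low``, after the bone
mineral density design the package emulates).  Each layer is a
feature x sample numeric matrix plus a binary group label per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("high", "low")


class CrossomicsError(Exception):
    """Base class for package errors."""


class ConfigurationError(CrossomicsError, ValueError):
    """Invalid configuration or precondition violation."""


class DegenerateDataError(CrossomicsError, ValueError):
    """Raised when a statistic is undefined for the given data."""


@dataclass
class OmicsMatrix:
    """One omics layer: numeric feature x sample matrix with group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Features in rows (unique index), samples in columns.  Normalised
        intensities on whatever (typically log2) scale the upstream
        processing produced; the analysis only uses within-feature
        contrasts so the scale is unitless here.
    groups : pandas.Series
        Maps every sample id to ``"high"`` or ``"low"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ConfigurationError(f"duplicate feature ids: {dup}")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()][:5].tolist()
            raise ConfigurationError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ConfigurationError(f"group labels must be in {GROUPS}, got {sorted(bad)}")
        if not all((self.groups == g).any() for g in GROUPS):
            raise ConfigurationError("both groups must be non-empty")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ConfigurationError("matrix values must be numeric")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def high_mask(self) -> np.ndarray:
        return (self.groups == "high").to_numpy()

    def same_samples_as(self, other: "OmicsMatrix") -> bool:
        return list(self.sample_ids) == list(other.sample_ids) and (
            self.groups.to_numpy() == other.groups.to_numpy()
        ).all()


@dataclass(frozen=True)
class PathwaySpec:
    """Pathway membership plus signed directed topology.

    ``topology`` rows are (source, target, beta) with beta in {+1, -1}
    (or any signed weight): +1 activation, -1 inhibition.
    """

    pathway_id: str
    members: frozenset[str]
    topology: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        for src, tgt, _ in self.topology:
            if src not in self.members or tgt not in self.members:
                raise ConfigurationError(
                    f"pathway {self.pathway_id}: topology edge ({src},{tgt}) "
                    "has endpoint outside membership"
                )

    @classmethod
    def from_lists(
        cls,
        pathway_id: str,
        members: Iterable[str],
        topology: Iterable[Sequence] = (),
    ) -> "PathwaySpec":
        return cls(
            pathway_id=pathway_id,
            members=frozenset(members),
            topology=tuple((str(s), str(t), float(b)) for s, t, b in topology),
        )


def as_layer_dict(layers: Mapping[str, OmicsMatrix]) -> dict[str, OmicsMatrix]:
    """Validate that all layers share the identical ordered sample design."""
    layers = dict(layers)
    if not layers:
        raise ConfigurationError("at least one omics layer is required")
    first = next(iter(layers.values()))
    for name, layer in layers.items():
        if not first.same_samples_as(layer):
            raise ConfigurationError(
                f"layer {name!r} does not share the sample design of the first layer"
            )
    return layers
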