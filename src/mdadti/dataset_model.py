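"""Core data types and text I/O for similarity matrices and the interaction matrix.

A dataset consists of one or more drug-drug similarity views, one or more
target-target similarity views, and a binary drug x target interaction
matrix.  Every matrix travels as a delimited text file with a header row of
column labels and an index column of row labels.  Matching of labels across
files is exact string equality; nothing is normalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mdadti")

# entries may stray outside [0,1] by this much before it is an error
BOUND_TOL = 1e-9


class FormatError(ValueError):
    """Malformed input file (non-square matrix, non-numeric body, ...)."""


class ValidationError(ValueError):
    """Well-formed input whose values violate a domain invariant."""


class AssemblyError(ValueError):
    """Label inconsistency between the parts of a dataset."""


def _check_labels(labels: list[str]) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate labels: {dupes}")
    return labels


def _clamp_unit_interval(values: np.ndarray, what: str) -> np.ndarray:
    """Clamp float dirt within BOUND_TOL of [0,1]; larger violations error."""
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what}: non-finite entries")
    if values.min() < -BOUND_TOL or values.max() > 1.0 + BOUND_TOL:
        bad = values[(values < -BOUND_TOL) | (values > 1.0 + BOUND_TOL)]
        raise ValidationError(
            f"{what}: entries outside [0,1], e.g. {bad.flat[0]!r}"
        )
    return np.clip(values, 0.0, 1.0)


@dataclass
class SimilarityView:
    """One modality's square similarity matrix with entity labels.

    ``values[i, j]`` scores the resemblance of entity ``labels[i]`` to
    ``labels[j]`` under this modality, on [0, 1].  Symmetry and a unit
    diagonal are typical but not required; asymmetry only logs a warning.
    """

    name: str
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise FormatError(
                f"view {self.name!r}: matrix must be square, got {self.values.shape}"
            )
        if self.values.shape[0] != len(self.labels):
            raise FormatError(
                f"view {self.name!r}: {len(self.labels)} labels for "
                f"{self.values.shape[0]} rows"
            )
        self.values = _clamp_unit_interval(self.values, f"view {self.name!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            logger.warning("similarity view %r is not symmetric", self.name)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class SimilaritySet:
    """Ordered collection of similarity views over one entity kind."""

    entity_kind: str  # "drug" | "target"
    views: list[SimilarityView]

    def __post_init__(self) -> None:
        if self.entity_kind not in ("drug", "target"):
            raise ValidationError(f"entity_kind must be drug|target, got {self.entity_kind!r}")
        if not self.views:
            raise ValidationError("similarity set needs at least one view")
        ref = self.views[0].labels
        for v in self.views[1:]:
            if v.labels != ref:
                raise ValidationError(
                    f"view {v.name!r} labels disagree with view {self.views[0].name!r}"
                )

    @property
    def labels(self) -> list[str]:
        return self.views[0].labels

    @property
    def n_views(self) -> int:
        return len(self.views)


@dataclass
class InteractionMatrix:
    """Binary drug x target interaction matrix Y; y[i, j] = 1 means drug i
    is a known interactor of target j, 0 means unknown (not confirmed negative)."""

    drug_labels: list[str]
    target_labels: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.drug_labels = _check_labels(self.drug_labels)
        self.target_labels = _check_labels(self.target_labels)
        y = np.asarray(self.y)
        if y.shape != (len(self.drug_labels), len(self.target_labels)):
            raise FormatError(
                f"interaction matrix shape {y.shape} does not match "
                f"{len(self.drug_labels)} drugs x {len(self.target_labels)} targets"
            )
        if not np.isin(y, (0, 1)).all():
            bad = y[~np.isin(y, (0, 1))]
            raise ValidationError(f"interaction entries must be 0/1, found {bad.flat[0]!r}")
        self.y = y.astype(np.int8)
        if self.n_positive == 0:
            logger.warning("interaction matrix has no positive entries")

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())


@dataclass
class Dataset:
    """Full problem instance: similarity views for both entity kinds plus Y."""

    drug_sims: SimilaritySet
    target_sims: SimilaritySet
    interactions: InteractionMatrix

    def __post_init__(self) -> None:
        if self.drug_sims.entity_kind != "drug":
            raise AssemblyError("drug_sims must have entity_kind='drug'")
        if self.target_sims.entity_kind != "target":
            raise AssemblyError("target_sims must have entity_kind='target'")
        if self.drug_sims.labels != self.interactions.drug_labels:
            raise AssemblyError("drug axis: similarity labels != interaction drug labels")
        if self.target_sims.labels != self.interactions.target_labels:
            raise AssemblyError("target axis: similarity labels != interaction target labels")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_sims.labels)

    @property
    def n_targets(self) -> int:
        return len(self.target_sims.labels)


# ---------------------------------------------------------------------------
# readers / writers (TSV with header row + index column; comma sniffed)
# ---------------------------------------------------------------------------

def _read_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:  # pragma: no cover - message wrapping
        raise FormatError(f"{path}: cannot parse delimited matrix: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError(f"{path}: non-numeric matrix body")
    return df


def read_similarity_view(path, name: str) -> SimilarityView:
    """Read one similarity modality from a delimited text matrix."""
    df = _read_matrix(path)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: similarity matrix must be square, got {df.shape}")
    return SimilarityView(name=name, labels=list(df.index.astype(str)), values=df.to_numpy(float))


def write_similarity_view(view: SimilarityView, path) -> None:
    df = pd.DataFrame(view.values, index=view.labels, columns=view.labels)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_interactions(path) -> InteractionMatrix:
    """Read the binary drug x target interaction matrix (drugs = rows)."""
    df = _read_matrix(path)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError(f"{path}: interaction entries must be 0 or 1")
    return InteractionMatrix(
        drug_labels=list(df.index.astype(str)),
        target_labels=list(df.columns.astype(str)),
        y=vals,
    )


def write_interactions(im: InteractionMatrix, path) -> None:
    df = pd.DataFrame(im.y, index=im.drug_labels, columns=im.target_labels)
    df.to_csv(path, sep="\t")


def assemble_dataset(
    drug_sims: SimilaritySet,
    target_sims: SimilaritySet,
    interactions: InteractionMatrix,
) -> Dataset:
    """Combine the parts into a validated :class:`Dataset`.

    Raises :class:`AssemblyError` naming the offending axis on any label
    mismatch (content or order).
    """
    return Dataset(drug_sims=drug_sims, target_sims=target_sims, interactions=interactions)
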