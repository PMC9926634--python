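"""Aligned multi-omics data containers and pre-training feature filtering.

The central container is :class:`MultiOmicsDataset`: an ordered collection of
per-view sample × feature matrices (gene expression, somatic mutation, copy
number aberration, ...) sharing one sample ordering, plus a binary drug
response vector (1 = responder, 0 = non-responder).

Matrices travel as TSV/CSV files with the sample ID in the first column and
gene IDs in the header row; the response file is a two-column table of
(sample ID, label).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsView",
    "ResponseVector",
    "MultiOmicsDataset",
    "variance_filter",
    "align",
    "read_view",
    "read_response",
    "write_dataset",
    "read_dataset",
    "EmptyViewError",
    "AlignmentError",
]


class EmptyViewError(ValueError):
    """Raised when a filter removes every feature of a view."""


class AlignmentError(ValueError):
    """Raised when sample IDs cannot be reconciled across inputs."""


@dataclass(frozen=True)
class OmicsView:
    """One omics modality: a samples × features matrix with gene identifiers.

    ``encoding`` is ``"continuous"`` (e.g. standardized expression) or
    ``"binary"`` (mutation / CNA status), in which case every entry must be
    0 or 1.
    """

    name: str
    matrix: np.ndarray
    feature_ids: tuple[str, ...]
    encoding: str = "continuous"
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if self.sample_ids is not None:
            object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if m.ndim != 2:
            raise ValueError(f"view {self.name!r}: matrix must be 2-D, got {m.ndim}-D")
        if len(self.feature_ids) != m.shape[1]:
            raise ValueError(
                f"view {self.name!r}: {len(self.feature_ids)} feature ids for "
                f"{m.shape[1]} matrix columns"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"view {self.name!r}: duplicate feature ids")
        if self.encoding not in ("continuous", "binary"):
            raise ValueError(f"view {self.name!r}: unknown encoding {self.encoding!r}")
        if self.encoding == "binary" and m.size and not np.isin(m, (0.0, 1.0)).all():
            raise ValueError(f"view {self.name!r}: binary encoding but entries outside {{0,1}}")
        if self.sample_ids is not None and len(self.sample_ids) != m.shape[0]:
            raise ValueError(f"view {self.name!r}: sample id count != row count")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ResponseVector:
    """Binary drug response labels keyed by sample ID (1 = responder)."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        y = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", y)
        if y.ndim != 1 or len(self.sample_ids) != y.shape[0]:
            raise ValueError("response: one label per sample id required")
        if y.size and not np.isin(y, (0, 1)).all():
            raise ValueError("response: labels must be 0/1")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("response: duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_responders(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class MultiOmicsDataset:
    """Ordered views sharing one sample ordering, plus the response vector."""

    views: tuple[OmicsView, ...]
    response: ResponseVector
    name: str = "dataset"

    def __post_init__(self):
        object.__setattr__(self, "views", tuple(self.views))
        if not self.views:
            raise ValueError("dataset needs at least one view")
        n = self.response.n_samples
        for v in self.views:
            if v.n_samples != n:
                raise ValueError(
                    f"view {v.name!r} has {v.n_samples} rows but response has {n}"
                )

    @property
    def n_samples(self) -> int:
        return self.response.n_samples

    @property
    def view_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.views)

    @property
    def labels(self) -> np.ndarray:
        return self.response.labels

    def view(self, name: str) -> OmicsView:
        for v in self.views:
            if v.name == name:
                return v
        raise KeyError(name)

    def matrices(self) -> list[np.ndarray]:
        return [v.matrix for v in self.views]

    def subset(self, idx: Sequence[int], name: str | None = None) -> "MultiOmicsDataset":
        """Row subset (e.g. a CV fold), preserving view structure."""
        idx = np.asarray(idx, dtype=int)
        views = tuple(
            replace(
                v,
                matrix=v.matrix[idx],
                sample_ids=None if v.sample_ids is None else tuple(np.asarray(v.sample_ids)[idx]),
            )
            for v in self.views
        )
        resp = ResponseVector(
            tuple(np.asarray(self.response.sample_ids)[idx]), self.response.labels[idx]
        )
        return MultiOmicsDataset(views, resp, name or self.name)


def variance_filter(view: OmicsView, threshold: float) -> OmicsView:
    """Drop features whose variance is not strictly above ``threshold``.

    Low-variance genes carry little discriminative information; removing them
    shrinks the input dimension before any model training.  Population
    variance (divide by n) is used: this is a filter, not an inference step.
    Column order of the survivors is preserved.
    """
    if threshold < 0:
        raise ValueError("variance threshold must be nonnegative")
    if view.n_features == 0:
        raise EmptyViewError(f"view {view.name!r} has no features to filter")
    var = view.matrix.var(axis=0)  # ddof=0: population variance
    keep = var > threshold
    if not keep.any():
        raise EmptyViewError(
            f"empty view after filtering: every feature of view {view.name!r} "
            f"has variance <= {threshold}"
        )
    return replace(
        view,
        matrix=view.matrix[:, keep],
        feature_ids=tuple(f for f, k in zip(view.feature_ids, keep) if k),
    )


def align(views: Iterable[OmicsView], response: ResponseVector,
          name: str = "dataset") -> MultiOmicsDataset:
    """Reorder every view's rows to the response's sample order.

    All inputs must carry the same *set* of sample IDs; the response order is
    the canonical one.  Views lacking sample IDs are assumed already aligned.
    """
    ref = response.sample_ids
    ref_set = set(ref)
    aligned = []
    for v in views:
        if v.sample_ids is None:
            if v.n_samples != response.n_samples:
                raise AlignmentError(
                    f"view {v.name!r} has no sample ids and a mismatched row count"
                )
            aligned.append(v)
            continue
        vset = set(v.sample_ids)
        if vset != ref_set:
            missing = sorted(ref_set - vset)
            extra = sorted(vset - ref_set)
            raise AlignmentError(
                f"view {v.name!r} sample ids disagree with response "
                f"(missing: {missing[:5]}, unexpected: {extra[:5]})"
            )
        pos = {s: i for i, s in enumerate(v.sample_ids)}
        order = np.array([pos[s] for s in ref], dtype=int)
        aligned.append(replace(v, matrix=v.matrix[order], sample_ids=ref))
    return MultiOmicsDataset(tuple(aligned), response, name)


# ---------------------------------------------------------------------------
# TSV/CSV interchange

def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_view(path: str | Path, name: str, encoding: str = "continuous") -> OmicsView:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return OmicsView(
        name=name,
        matrix=df.to_numpy(dtype=float),
        feature_ids=tuple(map(str, df.columns)),
        encoding=encoding,
        sample_ids=tuple(map(str, df.index)),
    )


def read_response(path: str | Path) -> ResponseVector:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] != 2:
        raise ValueError(f"response file {path} must have exactly two columns")
    return ResponseVector(tuple(map(str, df.iloc[:, 0])), df.iloc[:, 1].to_numpy())


def write_dataset(dataset: MultiOmicsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write one TSV per view plus ``response.tsv``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample_ids = list(dataset.response.sample_ids)
    paths: dict[str, Path] = {}
    for v in dataset.views:
        p = out / f"{v.name}.tsv"
        pd.DataFrame(v.matrix, index=sample_ids, columns=list(v.feature_ids)).to_csv(
            p, sep="\t", index_label="sample_id"
        )
        paths[v.name] = p
    rp = out / "response.tsv"
    pd.DataFrame({"sample_id": sample_ids, "response": dataset.labels}).to_csv(
        rp, sep="\t", index=False
    )
    paths["response"] = rp
    manifest = out / "views.json"
    manifest.write_text(json.dumps([[v.name, v.encoding] for v in dataset.views]))
    paths["views"] = manifest
    return paths


def read_dataset(directory: str | Path, view_specs: Sequence[tuple[str, str]] | None = None,
                 name: str = "dataset") -> MultiOmicsDataset:
    """Load a dataset written by :func:`write_dataset`.

    ``view_specs`` is a list of (view name, encoding); by default every
    ``*.tsv`` except ``response.tsv`` is loaded as continuous unless all its
    entries are 0/1, in which case it is marked binary.
    """
    directory = Path(directory)
    response = read_response(directory / "response.tsv")
    views = []
    if view_specs is None and (directory / "views.json").exists():
        view_specs = [tuple(v) for v in json.loads((directory / "views.json").read_text())]
    if view_specs is None:
        files = sorted(p for p in directory.glob("*.tsv") if p.name != "response.tsv")
        for p in files:
            v = read_view(p, p.stem)
            if v.matrix.size and np.isin(v.matrix, (0.0, 1.0)).all():
                v = replace(v, encoding="binary")
            views.append(v)
    else:
        for vname, enc in view_specs:
            views.append(read_view(directory / f"{vname}.tsv", vname, enc))
    return align(views, response, name)
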