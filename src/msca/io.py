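"""Delimited-matrix I/O and run configuration.

Views are exchanged as delimited text (TSV by default, CSV by extension):
first row = sample identifiers, first column = feature identifiers, numeric
body, oriented features x samples unless ``transposed`` is set. Labels are
two-column TSV (sample_id, cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .representation import OmicsView

__all__ = [
    "RunConfig",
    "read_view",
    "write_matrix",
    "read_matrix",
    "write_labels",
    "read_labels",
    "align_views",
]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (sufficient to reproduce it)."""

    view_paths: list[str]
    k_neighbors: int | None = None
    lam: float = 0.5
    num_clusters: int | str = 3
    fusion_iters: int = 30
    solver_tol: float = 1e-6
    fusion_tol: float = 1e-6
    seed: int = 0
    output_dir: str = "msca_out"
    zscore: bool = True
    normalize: bool = True
    renormalize: bool = True
    transposed: bool = False
    dump_intermediates: bool = False

    def __post_init__(self) -> None:
        if len(self.view_paths) < 2:
            raise ValueError("a run needs at least 2 view files")
        if self.lam <= 0 or self.fusion_iters < 1:
            raise ValueError("lam must be positive and fusion_iters >= 1")
        if self.solver_tol <= 0 or self.fusion_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.k_neighbors is not None and self.k_neighbors < 1:
            raise ValueError("k_neighbors must be positive")
        if self.num_clusters != "auto" and int(self.num_clusters) < 2:
            raise ValueError('num_clusters must be >= 2 or "auto"')

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_view(path: str | Path, transposed: bool = False, name: str | None = None) -> OmicsView:
    """Read one view from a delimited text matrix.

    The header row carries sample identifiers and the first column feature
    identifiers (swapped when ``transposed``). Any missing or non-numeric
    cell is rejected with its row/column coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if transposed:
        df = df.T
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    sample_ids = [str(s) for s in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample identifiers {dupes}")
    return OmicsView(
        values=body.to_numpy(dtype=float),
        sample_ids=sample_ids,
        view_name=name or path.stem,
    )


def write_matrix(M: np.ndarray, sample_ids: list[str], path: str | Path) -> None:
    """Write a sample x sample matrix with identifiers on both axes."""
    pd.DataFrame(M, index=sample_ids, columns=sample_ids).to_csv(
        path, sep=_sep_for(path)
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_labels(labels, sample_ids: list[str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "cluster": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "cluster"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_id and cluster")
    return df["cluster"].to_numpy(), [str(s) for s in df["sample_id"]]


def align_views(views: list[OmicsView]) -> list[OmicsView]:
    """Reorder all views to the first view's sample order, by identifier.

    Views with a different sample *set* are rejected before any computation;
    mere ordering differences are reconciled.
    """
    ref = views[0]
    ref_ids = list(ref.sample_ids)
    aligned = [ref]
    for v in views[1:]:
        if list(v.sample_ids) == ref_ids:
            aligned.append(v)
            continue
        if set(v.sample_ids) != set(ref_ids):
            missing = sorted(set(ref_ids) - set(v.sample_ids))[:5]
            extra = sorted(set(v.sample_ids) - set(ref_ids))[:5]
            raise ValueError(
                f"view {v.view_name!r} covers a different sample set "
                f"(missing {missing}, extra {extra})"
            )
        pos = {s: i for i, s in enumerate(v.sample_ids)}
        order = [pos[s] for s in ref_ids]
        aligned.append(
            OmicsView(values=v.values[:, order], sample_ids=ref_ids, view_name=v.view_name)
        )
    return aligned
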