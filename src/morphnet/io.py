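"""Reading and writing cohort tables, network matrices and ranked edge lists.

All files are UTF-8 delimited text with a mandatory header row; the delimiter
is auto-detected from the extension (``.tsv``/``.txt`` = tab, anything else =
comma).  Floats are written in shortest round-tripping repr, so a write/read
cycle reproduces values bit-exactly.  ROI and view indices in files are
1-based.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import ROIAtlas
from .cohort import CorticalAttributeCohort

__all__ = [
    "ParseError",
    "read_cohort",
    "write_cohort",
    "write_edge_list",
    "read_edge_list",
    "write_matrix",
    "read_matrix",
]


class ParseError(ValueError):
    """Malformed input file; carries the file and (1-based) line involved."""

    def __init__(self, message: str, path: str | Path, line: int | None = None):
        loc = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


def _delimiter(path: str | Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","


def read_cohort(
    attribute_paths: Mapping[str, str | Path] | Sequence[str | Path],
    metadata_path: str | Path,
    atlas: ROIAtlas,
) -> CorticalAttributeCohort:
    """Read a cohort from per-subject attribute tables plus a metadata table.

    Parameters
    ----------
    attribute_paths
        One attribute file per subject, either a mapping ``subject_id -> path``
        or a sequence aligned with metadata row order.  Each file has a header
        ``roi, <view 1>, ..., <view M>`` and one row per ROI in atlas order.
    metadata_path
        Table with columns ``subject_id, age, group, hemisphere``.
    atlas
        Expected ROI labels and order.

    Returns
    -------
    CorticalAttributeCohort
        Subjects in metadata row order.
    """
    meta_path = Path(metadata_path)
    try:
        meta = pd.read_csv(meta_path, sep=_delimiter(meta_path), dtype=str)
    except Exception as exc:  # pragma: no cover - passthrough of pandas detail
        raise ParseError(f"unreadable metadata table ({exc})", meta_path) from exc
    required = {"subject_id", "age", "group", "hemisphere"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"metadata missing columns {sorted(missing)}", meta_path)

    subject_ids: list[str] = []
    ages: list[float] = []
    for row_no, rec in enumerate(meta.itertuples(index=False), start=2):
        sid = str(rec.subject_id)
        if sid in subject_ids:
            raise ParseError(f"duplicate subject ID {sid!r}", meta_path, row_no)
        subject_ids.append(sid)
        try:
            ages.append(float(rec.age))
        except (TypeError, ValueError):
            raise ParseError(
                f"non-numeric age {rec.age!r} for subject {sid!r}", meta_path, row_no
            ) from None
    groups = [str(g) for g in meta["group"]]
    hemis = set(meta["hemisphere"])
    if len(hemis) != 1:
        raise ParseError(
            f"cohort must be single-hemisphere, found {sorted(hemis)}", meta_path
        )

    if isinstance(attribute_paths, Mapping):
        try:
            paths = [Path(attribute_paths[sid]) for sid in subject_ids]
        except KeyError as exc:
            raise ParseError(
                f"no attribute file given for subject {exc.args[0]!r}", meta_path
            ) from None
    else:
        paths = [Path(p) for p in attribute_paths]
        if len(paths) != len(subject_ids):
            raise ParseError(
                f"{len(paths)} attribute files for {len(subject_ids)} subjects",
                meta_path,
            )

    per_subject: list[np.ndarray] = []
    view_names: tuple[str, ...] | None = None
    for sid, path in zip(subject_ids, paths):
        values, names = _read_attribute_table(path, atlas)
        if view_names is None:
            view_names = names
        elif names != view_names:
            raise ParseError(
                f"view columns {list(names)} disagree with first subject's "
                f"{list(view_names)}",
                path,
            )
        per_subject.append(values)

    assert view_names is not None
    return CorticalAttributeCohort(
        subject_ids=subject_ids,
        ages=np.array(ages),
        groups=groups,
        hemisphere=next(iter(hemis)),
        attributes=np.stack(per_subject),  # (N, M, R)
        view_names=view_names,
    )


def _read_attribute_table(
    path: Path, atlas: ROIAtlas
) -> tuple[np.ndarray, tuple[str, ...]]:
    """One subject's table -> (M x R values, view names)."""
    sep = _delimiter(path)
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise ParseError("empty attribute file", path)
    header = [c.strip() for c in rows[0]]
    if not header or header[0].lower() != "roi":
        raise ParseError("first header column must be 'roi'", path, 1)
    names = tuple(header[1:])
    if not names:
        raise ParseError("no attribute columns after 'roi'", path, 1)

    data = np.full((len(names), atlas.count), np.nan)
    seen: set[str] = set()
    for line_no, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        label = row[0].strip()
        try:
            region = atlas.index_of(label)
        except KeyError:
            raise ParseError(f"unknown ROI label {label!r}", path, line_no) from None
        if label in seen:
            raise ParseError(f"duplicate ROI row {label!r}", path, line_no)
        seen.add(label)
        if len(row) != len(names) + 1:
            raise ParseError(
                f"expected {len(names) + 1} columns, found {len(row)}", path, line_no
            )
        for m, cell in enumerate(row[1:]):
            try:
                data[m, region - 1] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} in column {names[m]!r}",
                    path,
                    line_no,
                ) from None
    missing = [atlas.names[i] for i in range(atlas.count) if atlas.names[i] not in seen]
    if missing:
        raise ParseError(f"missing ROI rows: {missing}", path)
    return data, names


def write_cohort(
    cohort: CorticalAttributeCohort, out_dir: str | Path, atlas: ROIAtlas
) -> dict[str, Path]:
    """Write a cohort as a metadata table plus one attribute table per subject.

    Returns the mapping ``subject_id -> attribute file path`` (plus key
    ``"__metadata__"`` for the metadata table) so the output can be fed
    straight back into :func:`read_cohort`.
    """
    if atlas.count != cohort.n_rois:
        raise ValueError(
            f"{atlas.count}-ROI atlas does not match cohort with R={cohort.n_rois}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_path = out / "metadata.csv"
    pd.DataFrame(
        {
            "subject_id": cohort.subject_ids,
            "age": [repr(float(a)) for a in cohort.ages],
            "group": cohort.groups,
            "hemisphere": [cohort.hemisphere] * cohort.n_subjects,
        }
    ).to_csv(meta_path, index=False)

    paths: dict[str, Path] = {"__metadata__": meta_path}
    for k, sid in enumerate(cohort.subject_ids):
        path = out / f"{sid}_attributes.csv"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["roi", *cohort.view_names])
            for i, roi in enumerate(atlas.names):
                writer.writerow(
                    [roi, *(repr(float(v)) for v in cohort.attributes[k, :, i])]
                )
        paths[sid] = path
    return paths


def write_edge_list(
    edges: Iterable[tuple[int, int, int, float]],
    atlas: ROIAtlas,
    path: str | Path,
    view_names: Sequence[str] | None = None,
) -> None:
    """Write a ranked edge list as delimited text.

    Parameters
    ----------
    edges
        Tuples ``(view, roi_i, roi_j, relevance_score)`` with 1-based view
        and ROI indices and ``roi_i > roi_j``.  Lower relevance score =
        more age-predictive edge.
    atlas
        Resolves ROI indices to names.
    view_names
        Optional 1-based view labels; defaults to ``view<m>``.

    The output is sorted by ascending relevance score (best edge first) and
    carries an explicit ``rank`` column starting at 1.
    """
    rows = []
    for view, roi_i, roi_j, score in edges:
        for r in (roi_i, roi_j):
            if not 1 <= r <= atlas.count:
                raise ValueError(
                    f"ROI index {r} out of range for {atlas.count}-ROI atlas"
                )
        name = (
            view_names[view - 1]
            if view_names is not None
            else f"view{view}"
        )
        rows.append((name, view, roi_i, roi_j, float(score)))
    rows.sort(key=lambda r: (r[4], r[1], r[3], r[2]))

    path = Path(path)
    sep = _delimiter(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(
            [
                "view_name",
                "view",
                "roi_i_index",
                "roi_i_name",
                "roi_j_index",
                "roi_j_name",
                "relevance_score",
                "rank",
            ]
        )
        for rank, (name, view, roi_i, roi_j, score) in enumerate(rows, start=1):
            writer.writerow(
                [
                    name,
                    view,
                    roi_i,
                    atlas.name_of(roi_i),
                    roi_j,
                    atlas.name_of(roi_j),
                    repr(float(score)),
                    rank,
                ]
            )


def read_edge_list(path: str | Path) -> list[tuple[int, int, int, float]]:
    """Read back an edge list written by :func:`write_edge_list`.

    Returns ``(view, roi_i, roi_j, relevance_score)`` tuples in file (rank)
    order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path))
    return [
        (int(v), int(i), int(j), float(s))
        for v, i, j, s in zip(
            df["view"], df["roi_i_index"], df["roi_j_index"], df["relevance_score"]
        )
    ]


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write one R x R network matrix as headerless delimited text."""
    matrix = np.asarray(matrix, dtype=float)
    path = Path(path)
    sep = _delimiter(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        for row in matrix:
            writer.writerow([repr(float(v)) for v in row])


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [[float(c) for c in row] for row in csv.reader(fh, delimiter=_delimiter(path))]
    return np.array(rows)
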