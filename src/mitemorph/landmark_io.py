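"""Reading and writing landmark data.

The de-facto exchange format for 2-D landmark data in morphometrics is the
plain-text ``.tps`` dialect written by the tpsUtil/tpsDig digitizing family:
blocks starting with ``LM=<k>``, followed by *k* lines of two
whitespace-separated coordinates, optionally followed by ``IMAGE=``, ``ID=``
and ``SCALE=`` records.  Landmark coordinates are also commonly circulated as
spreadsheet workbooks whose rows mirror the tps line structure; both are
supported here and produce the same in-memory dataset.

Specimen-to-population/species labels live outside the tps file, in a mapping
table (CSV with columns ``specimen_id, population, species, excluded``) or,
as a fallback, in a regex applied to specimen IDs.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class TPSParseError(ValueError):
    """Malformed tps block (wrong coordinate count, bad record, ...)."""


class DatasetError(ValueError):
    """Inconsistent dataset (varying landmark counts, duplicate IDs, ...)."""


class LabelError(ValueError):
    """Specimen IDs that cannot be mapped to population/species labels."""


@dataclass
class LandmarkConfiguration:
    """One specimen's raw digitized landmarks.

    Parameters
    ----------
    specimen_id : str
        Unique identifier (from the ``ID=`` record or auto-numbered).
    coords : (k, 2) ndarray
        Planar landmark coordinates in digitized units (pixels or µm).
    scale : float, optional
        Physical units per coordinate unit (``SCALE=`` record), stored but
        not applied unless requested.
    image_ref : str, optional
        Source image name (``IMAGE=`` record).
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None
    image_ref: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DatasetError(
                f"specimen {self.specimen_id!r}: coords must be k x 2, "
                f"got shape {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise DatasetError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """An ordered collection of landmark configurations with group labels.

    ``excluded_from_stats`` holds specimens from singleton populations
    (n = 1): they take part in superimposition and appear in ordination
    plots as passively projected points, but are excluded from every
    statistical analysis.
    """

    configurations: list[LandmarkConfiguration]
    group_of: dict[str, str] = field(default_factory=dict)
    species_of: dict[str, str] = field(default_factory=dict)
    excluded_from_stats: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [c.specimen_id for c in self.configurations]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise DatasetError(f"duplicate specimen_ids: {sorted(dup)}")
        ks = {c.n_landmarks for c in self.configurations}
        if len(ks) > 1:
            raise DatasetError(f"inconsistent landmark counts across dataset: {sorted(ks)}")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def n_landmarks(self) -> int:
        if not self.configurations:
            raise DatasetError("empty dataset")
        return self.configurations[0].n_landmarks

    def coords_array(self) -> np.ndarray:
        """Stack raw coordinates as an (n, k, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def populations(self, specimen_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.specimen_ids if specimen_ids is None else list(specimen_ids)
        return np.array([self.group_of[i] for i in ids])

    def species(self, specimen_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.specimen_ids if specimen_ids is None else list(specimen_ids)
        return np.array([self.species_of[i] for i in ids])

    def subset(self, specimen_ids: Iterable[str]) -> "LandmarkDataset":
        keep = set(specimen_ids)
        configs = [c for c in self.configurations if c.specimen_id in keep]
        return LandmarkDataset(
            configurations=configs,
            group_of={i: g for i, g in self.group_of.items() if i in keep},
            species_of={i: s for i, s in self.species_of.items() if i in keep},
            excluded_from_stats=self.excluded_from_stats & keep,
        )

    def with_labels(
        self,
        mapping: pd.DataFrame | Mapping[str, tuple[str, str]],
        *,
        autodetect_singletons: bool = True,
    ) -> "LandmarkDataset":
        """Return a copy of the dataset with population/species labels attached.

        ``mapping`` is either a DataFrame with columns
        ``specimen_id, population, species`` (optional boolean ``excluded``)
        or a dict ``specimen_id -> (population, species)``.

        With ``autodetect_singletons`` (default), populations of size 1 are
        flagged ``excluded_from_stats`` even when the table carries no
        ``excluded`` column.
        """
        if isinstance(mapping, pd.DataFrame):
            df = mapping.astype({"specimen_id": str})
            pop = dict(zip(df["specimen_id"], df["population"].astype(str)))
            spc = dict(zip(df["specimen_id"], df["species"].astype(str)))
            excl = set()
            if "excluded" in df.columns:
                flag = df["excluded"].astype(str).str.lower().isin(["1", "true", "yes"])
                excl = set(df.loc[flag, "specimen_id"])
        else:
            pop = {i: ps[0] for i, ps in mapping.items()}
            spc = {i: ps[1] for i, ps in mapping.items()}
            excl = set()

        missing = [i for i in self.specimen_ids if i not in pop or i not in spc]
        if missing:
            raise LabelError(f"unmappable specimen IDs: {missing}")
        group_of = {i: pop[i] for i in self.specimen_ids}
        species_of = {i: spc[i] for i in self.specimen_ids}
        if autodetect_singletons:
            counts: dict[str, int] = {}
            for g in group_of.values():
                counts[g] = counts.get(g, 0) + 1
            excl |= {i for i, g in group_of.items() if counts[g] == 1}
        return LandmarkDataset(
            configurations=list(self.configurations),
            group_of=group_of,
            species_of=species_of,
            excluded_from_stats=excl & set(self.specimen_ids),
        )

    def label_by_regex(self, pattern: str) -> "LandmarkDataset":
        """Derive labels from specimen IDs via a regex with named groups
        ``species`` and ``population`` (fallback when no mapping table
        exists)."""
        rx = re.compile(pattern)
        mapping = {}
        bad = []
        for i in self.specimen_ids:
            m = rx.match(i)
            if m is None:
                bad.append(i)
            else:
                mapping[i] = (m.group("population"), m.group("species"))
        if bad:
            raise LabelError(f"IDs not matching label pattern: {bad}")
        return self.with_labels(mapping)


# ---------------------------------------------------------------------------
# tps text format


def _parse_tps_lines(lines: Iterable[str]) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    pending_k: int | None = None
    coords: list[list[float]] = []
    meta: dict[str, str] = {}
    block_index = 0

    def flush() -> None:
        nonlocal pending_k, coords, meta, block_index
        if pending_k is None:
            return
        if len(coords) != pending_k:
            raise TPSParseError(
                f"block {block_index}: expected {pending_k} coordinate lines, "
                f"got {len(coords)}"
            )
        sid = meta.get("ID", str(block_index))
        scale = float(meta["SCALE"]) if "SCALE" in meta else None
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid,
                coords=np.array(coords, dtype=float),
                scale=scale,
                image_ref=meta.get("IMAGE"),
            )
        )
        pending_k, coords, meta = None, [], {}
        block_index += 1

    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            flush()
            try:
                pending_k = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise TPSParseError(f"block {block_index}: bad LM record {line!r}") from exc
        elif "=" in line and not _looks_like_coords(line):
            key, val = line.split("=", 1)
            meta[key.strip().upper()] = val.strip()
        else:
            if pending_k is None:
                raise TPSParseError(f"coordinate line outside any LM= block: {line!r}")
            parts = line.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"block {block_index}: coordinate line needs 2 values, got {line!r}"
                )
            coords.append([float(parts[0]), float(parts[1])])
    flush()
    return configs


def _looks_like_coords(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def read_tps(path: str | Path, *, apply_scale: bool = False) -> LandmarkDataset:
    """Parse a tps file into a :class:`LandmarkDataset`.

    ``SCALE=`` records are stored on each configuration; coordinates are
    multiplied by the scale only when ``apply_scale=True`` (shape analysis is
    scale-invariant after superimposition, so raw digitized units are the
    default).
    """
    text = Path(path).read_text()
    configs = _parse_tps_lines(io.StringIO(text))
    if apply_scale:
        for c in configs:
            if c.scale is not None:
                c.coords = c.coords * c.scale
    return LandmarkDataset(configurations=configs)


def write_tps(dataset: LandmarkDataset, path: str | Path, *, decimals: int = 5) -> None:
    """Write a dataset as tps text (5 decimals, matching tpsDig granularity)."""
    if not dataset.configurations:
        raise DatasetError("refusing to write an empty dataset")
    lines: list[str] = []
    for c in dataset.configurations:
        lines.append(f"LM={c.n_landmarks}")
        for x, y in c.coords:
            lines.append(f"{x:.{decimals}f} {y:.{decimals}f}")
        if c.image_ref:
            lines.append(f"IMAGE={c.image_ref}")
        lines.append(f"ID={c.specimen_id}")
        if c.scale is not None:
            lines.append(f"SCALE={c.scale}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# spreadsheet (workbook) layout


def read_supplementary_xlsx(
    path: str | Path,
    mapping: pd.DataFrame | None = None,
    *,
    sheet: int | str = 0,
    id_pattern: str | None = None,
) -> LandmarkDataset:
    """Read a workbook whose rows reproduce tps-structured lines.

    Each row is joined into a text line (cells separated by whitespace) and
    the result is parsed exactly like a tps file, so a workbook and its tps
    twin yield identical datasets.  Labels are attached from ``mapping``
    (CSV-style DataFrame) or, failing that, from an ``id_pattern`` regex.
    """
    from openpyxl import load_workbook

    wb = load_workbook(Path(path), read_only=True, data_only=True)
    ws = wb[wb.sheetnames[sheet]] if isinstance(sheet, int) else wb[sheet]
    lines = []
    for row in ws.iter_rows(values_only=True):
        cells = [str(c) for c in row if c is not None and str(c).strip() != ""]
        if cells:
            lines.append(" ".join(cells))
    wb.close()
    ds = LandmarkDataset(configurations=_parse_tps_lines(lines))
    if mapping is not None:
        return ds.with_labels(mapping)
    if id_pattern is not None:
        return ds.label_by_regex(id_pattern)
    return ds


def write_supplementary_xlsx(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a dataset in the tps-rows-in-a-spreadsheet layout."""
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    for c in dataset.configurations:
        ws.append([f"LM={c.n_landmarks}"])
        for x, y in c.coords:
            ws.append([float(x), float(y)])
        if c.image_ref:
            ws.append([f"IMAGE={c.image_ref}"])
        ws.append([f"ID={c.specimen_id}"])
        if c.scale is not None:
            ws.append([f"SCALE={c.scale}"])
    wb.save(Path(path))


def read_mapping_csv(path: str | Path) -> pd.DataFrame:
    """Read a specimen-to-labels mapping table (specimen_id, population,
    species[, excluded])."""
    df = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "population", "species"}
    missing = required - set(df.columns)
    if missing:
        raise LabelError(f"mapping table missing columns: {sorted(missing)}")
    return df
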