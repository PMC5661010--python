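"""Core domain types and plain-text IO for the fingerprinting pipeline.

The pipeline's central container is the :class:`BucketTable` — a samples ×
buckets intensity matrix in which each bucket is a contiguous ppm interval of
a 1D NMR spectrum, optionally annotated with the metabolite it was assigned
to.  Sample metadata maps each sample to its experimental condition (protein ×
aggregation state) and replicate structure; a :class:`PathwayLibrary` holds
compound-membership sets for over-representation testing.

ppm axes follow the standard NMR display convention: descending left to
right, so a bucket is stored as ``(ppm_left, ppm_right)`` with
``ppm_left > ppm_right``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "Bucket",
    "BucketTable",
    "SampleMetadata",
    "PathwayLibrary",
    "PROTEINS",
    "CONFORMATIONS",
    "read_bucket_table",
    "write_bucket_table",
    "read_metadata",
    "write_metadata",
    "read_pathway_library",
    "write_pathway_library",
    "derive_group_labels",
]

PROTEINS = ("none", "abeta40", "abeta42", "asyn")
CONFORMATIONS = ("control", "monomer", "oligomer", "fibril")


@dataclass
class Spectrum:
    """One processed 1D NMR trace.

    Parameters
    ----------
    sample_id
        Identifier of the sample the spectrum belongs to.
    ppm
        Chemical-shift axis in ppm, strictly monotone.  Either direction is
        accepted on input; the stored axis is normalized to descending
        (standard display convention).
    intensity
        Intensities in arbitrary units, same length as ``ppm``.
    spectrometer_freq
        Proton Larmor frequency in MHz (e.g. 600.13); converts ppm linewidths
        to Hz.
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    spectrometer_freq: float

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.size < 2:
            raise ValueError("ppm axis must be a 1-D array with >= 2 points")
        if self.intensity.shape != self.ppm.shape:
            raise ValueError("ppm and intensity must have equal length")
        if not self.spectrometer_freq > 0:
            raise ValueError("spectrometer_freq must be > 0 (MHz)")
        d = np.diff(self.ppm)
        if np.all(d > 0):  # ascending input: flip to descending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError("ppm axis must be strictly monotone")


@dataclass(frozen=True)
class Bucket:
    """A ppm interval whose integrated intensity is one fingerprint feature."""

    bucket_id: str
    ppm_left: float
    ppm_right: float
    annotation: str | None = None       # metabolite name, if assigned
    metabolite_id: str | None = None    # compound ID used for enrichment

    def __post_init__(self) -> None:
        if not self.ppm_left > self.ppm_right:
            raise ValueError(
                f"bucket {self.bucket_id!r}: ppm_left ({self.ppm_left}) must be "
                f"> ppm_right ({self.ppm_right}) (descending ppm convention)"
            )

    @property
    def width(self) -> float:
        return self.ppm_left - self.ppm_right

    @property
    def center(self) -> float:
        return 0.5 * (self.ppm_left + self.ppm_right)


class BucketTable:
    """Samples × buckets intensity matrix with ppm ranges and annotations."""

    def __init__(
        self,
        samples: Sequence[str],
        buckets: Sequence[Bucket],
        values: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.buckets = list(buckets)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.buckets)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.samples)} samples, {len(self.buckets)} buckets)"
            )
        if np.isnan(self.values).any():
            raise ValueError("bucket table contains missing values")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs in bucket table")
        if len({b.bucket_id for b in self.buckets}) != len(self.buckets):
            raise ValueError("duplicate bucket IDs in bucket table")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_buckets(self) -> int:
        return len(self.buckets)

    @property
    def bucket_ids(self) -> list[str]:
        return [b.bucket_id for b in self.buckets]

    def annotation_map(self) -> dict[str, list[str]]:
        """Map metabolite name -> list of bucket IDs assigned to it."""
        out: dict[str, list[str]] = {}
        for b in self.buckets:
            if b.annotation:
                out.setdefault(b.annotation, []).append(b.bucket_id)
        return out

    def subset_samples(self, sample_ids: Sequence[str]) -> "BucketTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return BucketTable(list(sample_ids), self.buckets, self.values[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.bucket_ids)

    def __repr__(self) -> str:  # pragma: no cover
        return f"BucketTable({self.n_samples} samples x {self.n_buckets} buckets)"


@dataclass(frozen=True)
class SampleMetadata:
    """Condition and replicate structure for one sample.

    ``protein`` is one of none/abeta40/abeta42/asyn and ``conformation`` one
    of control/monomer/oligomer/fibril; ``protein == "none"`` if and only if
    ``conformation == "control"``.
    """

    sample_id: str
    protein: str
    conformation: str
    bio_rep: int
    tech_rep: int

    def __post_init__(self) -> None:
        if self.protein not in PROTEINS:
            raise ValueError(f"unknown protein {self.protein!r}")
        if self.conformation not in CONFORMATIONS:
            raise ValueError(f"unknown conformation {self.conformation!r}")
        if (self.protein == "none") != (self.conformation == "control"):
            raise ValueError(
                f"sample {self.sample_id!r}: protein 'none' and conformation "
                "'control' must occur together"
            )
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValueError("replicate indices must be >= 1")

    @property
    def condition(self) -> str:
        if self.conformation == "control":
            return "control"
        return f"{self.protein}_{self.conformation}"


class PathwayLibrary:
    """Compound-membership sets defining the enrichment universe."""

    def __init__(
        self,
        pathways: Mapping[str, tuple[str, frozenset[str]]],
        universe: set[str] | None = None,
        types: Mapping[str, str] | None = None,
    ) -> None:
        self.pathways = {k: (name, frozenset(members)) for k, (name, members) in pathways.items()}
        for pid, (_, members) in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")
        union: set[str] = set()
        for _, members in self.pathways.values():
            union |= members
        if universe is None:
            self.universe = union
        else:
            missing = union - set(universe)
            if missing:
                raise ValueError(
                    f"{len(missing)} pathway members missing from supplied universe "
                    f"(e.g. {sorted(missing)[:3]})"
                )
            self.universe = set(universe)
        self.types = dict(types or {})

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.pathways[pathway_id][0]

    def __repr__(self) -> str:  # pragma: no cover
        return f"PathwayLibrary({self.n_pathways} pathways, {len(self.universe)} compounds)"


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_PPM_RANGE_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*\.\.\s*(-?\d+(?:\.\d+)?)\s*$")


def _sniff_sep(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def parse_bucket_id(bucket_id: str) -> tuple[float, float]:
    """Parse a ``"9.850..9.820"`` style bucket ID into (ppm_left, ppm_right)."""
    m = _PPM_RANGE_RE.match(bucket_id)
    if not m:
        raise ValueError(f"unparsable ppm range in bucket ID {bucket_id!r}")
    left, right = float(m.group(1)), float(m.group(2))
    return left, right


def read_bucket_table(path: str | Path) -> BucketTable:
    """Read a bucket table from delimited text (comma or tab, auto-detected).

    Layout: row 1 = ``sample_id`` followed by bucket IDs encoding ppm ranges
    as ``"<high>..<low>"``; optional row 2 (first cell ``annotation``) =
    metabolite annotations, each either ``name`` or ``name|compound_id``;
    remaining rows = one sample each.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty bucket table")
    sep = _sniff_sep(lines[0])
    header = lines[0].split(sep)
    bucket_ids = [h.strip() for h in header[1:]]
    if not bucket_ids:
        raise ValueError(f"{path}: header row has no bucket IDs")

    annotations: list[tuple[str | None, str | None]] = [(None, None)] * len(bucket_ids)
    data_start = 1
    if len(lines) > 1 and lines[1].split(sep)[0].strip().lower() == "annotation":
        cells = lines[1].split(sep)[1:]
        if len(cells) != len(bucket_ids):
            raise ValueError(
                f"{path}: annotation row has {len(cells)} cells, expected {len(bucket_ids)}"
            )
        parsed = []
        for c in cells:
            c = c.strip()
            if not c:
                parsed.append((None, None))
            elif "|" in c:
                name, cid = c.split("|", 1)
                parsed.append((name.strip() or None, cid.strip() or None))
            else:
                parsed.append((c, None))
        annotations = parsed
        data_start = 2

    buckets = []
    for j, bid in enumerate(bucket_ids):
        try:
            left, right = parse_bucket_id(bid)
        except ValueError as exc:
            raise ValueError(f"{path}: column {j + 2}: {exc}") from exc
        ann, cid = annotations[j]
        buckets.append(Bucket(bid, left, right, annotation=ann, metabolite_id=cid))

    samples: list[str] = []
    rows: list[list[float]] = []
    for i, line in enumerate(lines[data_start:], start=data_start + 1):
        cells = line.split(sep)
        if len(cells) != len(bucket_ids) + 1:
            raise ValueError(
                f"{path}: row {i}: expected {len(bucket_ids) + 1} cells, got {len(cells)}"
            )
        sid = cells[0].strip()
        if sid in samples:
            raise ValueError(f"{path}: row {i}: duplicate sample ID {sid!r}")
        samples.append(sid)
        row = []
        for j, c in enumerate(cells[1:]):
            if not c.strip():
                raise ValueError(
                    f"{path}: missing value at row {i}, column {j + 2} "
                    f"(sample {sid!r}, bucket {bucket_ids[j]!r})"
                )
            try:
                row.append(float(c))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unparsable value {c!r} at row {i}, column {j + 2}"
                ) from exc
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no sample rows")
    return BucketTable(samples, buckets, np.asarray(rows, dtype=float))


def write_bucket_table(table: BucketTable, path: str | Path, sep: str = "\t") -> None:
    """Write a bucket table as delimited text; floats use shortest round-trip
    representation so read(write(x)) is bitwise-identical."""
    path = Path(path)
    lines = ["sample_id" + sep + sep.join(table.bucket_ids)]
    if any(b.annotation or b.metabolite_id for b in table.buckets):
        cells = []
        for b in table.buckets:
            if b.metabolite_id:
                cells.append(f"{b.annotation or ''}|{b.metabolite_id}")
            else:
                cells.append(b.annotation or "")
        lines.append("annotation" + sep + sep.join(cells))
    for i, sid in enumerate(table.samples):
        lines.append(sid + sep + sep.join(repr(float(v)) for v in table.values[i]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata from delimited text with columns
    sample_id, protein, conformation, bio_rep, tech_rep."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "protein", "conformation", "bio_rep", "tech_rep"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    records = [
        SampleMetadata(
            sample_id=str(r.sample_id),
            protein=str(r.protein),
            conformation=str(r.conformation),
            bio_rep=int(r.bio_rep),
            tech_rep=int(r.tech_rep),
        )
        for r in df.itertuples()
    ]
    ids = [m.sample_id for m in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample IDs in metadata")
    return records


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "protein": [m.protein for m in metadata],
            "conformation": [m.conformation for m in metadata],
            "bio_rep": [m.bio_rep for m in metadata],
            "tech_rep": [m.tech_rep for m in metadata],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pathway_library(
    path: str | Path, universe: Iterable[str] | None = None
) -> PathwayLibrary:
    """Read a GMT-style pathway library.

    Each line is ``pathway_id TAB name TAB member1 TAB member2 ...``.  As an
    extension, a third token of the form ``type=<text>`` is read as
    pathway-type metadata (used for type-grouped ranking); members follow it.
    Unless an explicit universe is supplied, the universe is the union of all
    members.
    """
    path = Path(path)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    types: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (id, name, members...), got {len(fields)}"
                )
            pid, name = fields[0], fields[1]
            rest = fields[2:]
            if rest and rest[0].startswith("type="):
                types[pid] = rest[0][len("type="):]
                rest = rest[1:]
            members = frozenset(m for m in rest if m.strip())
            if not members:
                raise ValueError(f"{path}: line {lineno}: pathway {pid!r} has no members")
            if pid in pathways:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway ID {pid!r}")
            pathways[pid] = (name, members)
    if not pathways:
        raise ValueError(f"{path}: no pathways")
    return PathwayLibrary(pathways, universe=set(universe) if universe is not None else None,
                          types=types)


def write_pathway_library(library: PathwayLibrary, path: str | Path) -> None:
    """Write a library in the GMT dialect read by :func:`read_pathway_library`."""
    lines = []
    for pid in sorted(library.pathways):
        name, members = library.pathways[pid]
        fields = [pid, name]
        if pid in library.types:
            fields.append(f"type={library.types[pid]}")
        fields += sorted(members)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def derive_group_labels(
    metadata: Sequence[SampleMetadata], design: str
) -> dict[str, str]:
    """Derive per-sample group labels for a discriminant design.

    ``design="conformation"`` labels each sample by aggregation state alone
    (control/monomer/oligomer/fibril, 4 groups in the full study design);
    ``design="combined"`` labels by protein × conformation (control plus
    3 proteins × 3 conformations, 10 groups).
    """
    if not metadata:
        raise ValueError("metadata is empty")
    if design == "conformation":
        return {m.sample_id: m.conformation for m in metadata}
    if design == "combined":
        return {m.sample_id: m.condition for m in metadata}
    raise ValueError(f"unknown design {design!r} (expected 'conformation' or 'combined')")
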