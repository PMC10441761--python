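"""Core genomic data types and plain-text readers/writers.

Every coordinate in this package is 0-based, half-open ``[start, end)`` —
the native convention of BED and bedGraph. GFF3 (1-based, inclusive) is
converted at the file boundary and never leaks inward. Chromosome names are
taken verbatim; a naming mismatch between files is an error to surface, not
something to paper over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SampleSheet",
    "SignalTrack",
    "BedFormatError",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_count_matrix",
    "write_count_matrix",
    "GROUPS_T1",
    "GROUPS_T2",
    "ASSAYS",
]

GROUPS_T1 = frozenset({"NC", "HFD"})
GROUPS_T2 = frozenset({"NC-NC", "HFD-NC"})
ASSAYS = frozenset({"RNA", "ATAC", "K27ac", "K27me3", "K9me3"})


class BedFormatError(ValueError):
    """A malformed record in a BED-family file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on one chromosome.

    Sort order is (chrom, start, end); the optional ``id`` does not take
    part in comparisons.
    """

    chrom: str
    start: int
    end: int
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site.

    ``tss`` is the first transcribed base: ``span.start`` on the + strand,
    ``span.end - 1`` on the − strand (the last base of the half-open span).
    """

    gene_id: str
    span: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1


class SampleSheet:
    """Validated table of samples: assay × diet group × timepoint × replicate.

    The study design ties the group label to the timepoint: NC/HFD exist only
    at T1 (end of the diet phase) and NC-NC/HFD-NC only at T2 (after the
    reversal phase). Construction enforces that coupling.
    """

    COLUMNS = ("sample_id", "assay", "group", "timepoint", "replicate")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if frame["sample_id"].duplicated().any():
            dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id: {sorted(set(dupes))}")
        bad_assay = set(frame["assay"]) - ASSAYS
        if bad_assay:
            raise ValueError(f"unknown assay values: {sorted(bad_assay)}")
        for _, row in frame.iterrows():
            g, t = row["group"], row["timepoint"]
            ok = (g in GROUPS_T1 and t == "T1") or (g in GROUPS_T2 and t == "T2")
            if not ok:
                raise ValueError(
                    f"sample {row['sample_id']}: group {g!r} is inconsistent "
                    f"with timepoint {t!r} (NC/HFD are T1; NC-NC/HFD-NC are T2)"
                )
        if (frame["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be >= 1")
        frame["replicate"] = frame["replicate"].astype(int)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def sample_ids(
        self,
        assay: str | None = None,
        group: str | None = None,
        timepoint: str | None = None,
    ) -> list[str]:
        f = self.frame
        if assay is not None:
            f = f[f["assay"] == assay]
        if group is not None:
            f = f[f["group"] == group]
        if timepoint is not None:
            f = f[f["timepoint"] == timepoint]
        return list(f["sample_id"])


class SignalTrack:
    """Per-chromosome sorted, non-overlapping intervals with non-negative values.

    Backed by numpy arrays (starts, ends, values) per chromosome.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: ragged track arrays")
            if np.any(starts >= ends) or np.any(starts < 0):
                raise ValueError(f"{chrom}: invalid interval bounds")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative signal value")
            if len(starts) > 1:
                order = np.lexsort((ends, starts))
                starts, ends, values = starts[order], ends[order], values[order]
                if np.any(starts[1:] < ends[:-1]):
                    i = int(np.argmax(starts[1:] < ends[:-1]))
                    raise ValueError(
                        f"{chrom}: overlapping track intervals near "
                        f"{starts[i + 1]} < {ends[i]}"
                    )
            self.data[chrom] = (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[GenomicInterval, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in records:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
        data = {}
        for chrom, rows in by_chrom.items():
            s, e, v = zip(*rows)
            data[chrom] = (np.array(s), np.array(e), np.array(v, dtype=float))
        return cls(data)

    def chroms(self) -> list[str]:
        return list(self.data)

    def records(self) -> list[tuple[GenomicInterval, float]]:
        out = []
        for chrom in self.data:
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                out.append((GenomicInterval(chrom, int(s), int(e)), float(v)))
        return out

    def scale(self, factor: float) -> "SignalTrack":
        """Return a copy with every value multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self.data.items()}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self.data) != set(other.data):
            return False
        for c in self.data:
            s1, e1, v1 = self.data[c]
            s2, e2, v2 = other.data[c]
            if not (
                np.array_equal(s1, s2)
                and np.array_equal(e1, e2)
                and np.allclose(v1, v2, rtol=0, atol=5e-7)
            ):
                return False
        return True


# ---------------------------------------------------------------------------
# readers / writers


def read_bed(path: str | Path, skip_bad_records: bool = False) -> list[GenomicInterval]:
    """Read a BED3+ file, preserving file order.

    The optional 4th column becomes the interval id. Malformed lines raise
    :class:`BedFormatError` with the 1-based line number; with
    ``skip_bad_records`` they are dropped with a warning instead. Non-integer
    coordinates always reject the file.
    """
    intervals: list[GenomicInterval] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name))
            except ValueError as exc:
                if skip_bad_records:
                    n_bad += 1
                    continue
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    if n_bad:
        warnings.warn(f"{path}: skipped {n_bad} malformed BED line(s)")
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    scores: Sequence[int | float] | None = None,
) -> None:
    """Write BED3/BED4; with ``scores``, BED5 (name defaults to '.')."""
    if scores is not None and len(scores) != len(intervals):
        raise ValueError("scores length must match intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if scores is not None:
                cols += [iv.id or ".", str(scores[i])]
            elif iv.id is not None:
                cols.append(iv.id)
            fh.write("\t".join(cols) + "\n")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_table(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or a TSV gene table.

    ``format`` is ``"gff3"`` or ``"tsv"``; by default it is inferred from the
    file suffix. GFF3 is 1-based inclusive and only ``gene`` features are
    consumed; the TSV table has columns (gene_id, chrom, start, end, strand)
    in 0-based half-open coordinates. Duplicate gene ids and unknown strand
    symbols are hard errors.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    genes: list[GeneModel] = []
    seen: set[str] = set()

    def _add(gene_id: str, chrom: str, start: int, end: int, strand: str) -> None:
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        genes.append(GeneModel(gene_id, GenomicInterval(chrom, start, end), strand))

    if format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: not a GFF3 record")
                if fields[2] != "gene":
                    continue
                attrs = _parse_gff3_attributes(fields[8])
                gene_id = attrs.get("ID") or attrs.get("gene_id")
                if gene_id is None:
                    raise ValueError(f"{path}:{lineno}: gene record without ID")
                # 1-based inclusive -> 0-based half-open
                _add(gene_id, fields[0], int(fields[3]) - 1, int(fields[4]), fields[6])
    elif format == "tsv":
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        needed = {"gene_id", "chrom", "start", "end", "strand"}
        if not needed <= set(table.columns):
            raise ValueError(f"gene table missing columns {needed - set(table.columns)}")
        for _, row in table.iterrows():
            _add(
                str(row["gene_id"]),
                row["chrom"],
                int(row["start"]),
                int(row["end"]),
                str(row["strand"]),
            )
    else:
        raise ValueError(f"unknown gene table format {format!r}")
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "epimemo",
                        "gene",
                        str(g.span.start + 1),
                        str(g.span.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.span.start for g in genes],
            "end": [g.span.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


BEDGRAPH_DECIMALS = 6


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping intervals or negative values are errors.
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(f"{path}:{lineno}: fewer than 4 columns")
            value = float(fields[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative bedGraph value")
            by_chrom.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), value)
            )
    data = {}
    for chrom, rows in by_chrom.items():
        s, e, v = zip(*rows)
        data[chrom] = (np.array(s), np.array(e), np.array(v, dtype=float))
    return SignalTrack(data)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a bedGraph with values rounded to 6 decimal places."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.{BEDGRAPH_DECIMALS}f}\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame["replicate"] = frame["replicate"].astype(int)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    sizes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, length = line.split("\t")[:2]
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length")
            sizes.append((chrom, length))
    return sizes


def write_chrom_sizes(sizes: Sequence[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes:
            fh.write(f"{chrom}\t{length}\n")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features × samples integer count TSV (first column feature_id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if (frame.values < 0).any():
        raise ValueError("negative counts in matrix")
    return frame.astype(np.int64)


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")
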