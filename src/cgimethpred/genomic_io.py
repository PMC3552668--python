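"""Genomic data model, file readers/writers and run configuration.

Everything downstream works on the types defined here: contigs, 0-based
half-open genomic intervals, step-function numeric tracks (bedGraph
semantics, value 0 outside covered steps), per-CpG bisulfite calls, and the
track manifest that names every annotation resource the feature extractor
consumes (conserved TFBS groups, conserved elements, histone
methylation/acetylation tag tracks, nucleosome occupancy tracks, repeats,
genes, cancer-process gene sets, dinucleotide conformational tables).

Coordinate convention: 0-based half-open throughout (BED convention).  A CpG
position refers to the C of the CpG dinucleotide on the forward strand.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("cgimethpred")

VALID_BASES = frozenset("ACGTN")

#: Representative average B-DNA helical step parameters per dinucleotide
#: (synthetic defaults; the six tables are editable inputs and ship with the
#: fixture bundle).  Units: twist/tilt/roll in degrees, shift/slide/rise in
#: Angstrom.
DEFAULT_DINUCLEOTIDE_PROPERTIES: dict[str, dict[str, float]] = {
    "twist": {
        "AA": 35.6, "AC": 32.9, "AG": 27.8, "AT": 31.5,
        "CA": 34.5, "CC": 33.7, "CG": 29.8, "CT": 27.8,
        "GA": 36.9, "GC": 40.0, "GG": 33.7, "GT": 32.9,
        "TA": 36.0, "TC": 36.9, "TG": 34.5, "TT": 35.6,
    },
    "tilt": {
        "AA": -0.4, "AC": -0.9, "AG": -2.6, "AT": 0.0,
        "CA": 0.6, "CC": -1.1, "CG": 0.0, "CT": 2.6,
        "GA": -1.5, "GC": 0.0, "GG": 1.1, "GT": 0.9,
        "TA": 0.0, "TC": 1.5, "TG": -0.6, "TT": 0.4,
    },
    "roll": {
        "AA": 0.7, "AC": 0.7, "AG": 4.5, "AT": 1.1,
        "CA": 4.7, "CC": 3.6, "CG": 5.4, "CT": 4.5,
        "GA": 1.9, "GC": 0.3, "GG": 3.6, "GT": 0.7,
        "TA": 3.3, "TC": 1.9, "TG": 4.7, "TT": 0.7,
    },
    "shift": {
        "AA": -0.03, "AC": 0.13, "AG": 0.09, "AT": 0.00,
        "CA": 0.09, "CC": 0.05, "CG": 0.00, "CT": -0.09,
        "GA": -0.28, "GC": 0.00, "GG": -0.05, "GT": -0.13,
        "TA": 0.00, "TC": 0.28, "TG": -0.09, "TT": 0.03,
    },
    "slide": {
        "AA": -0.08, "AC": -0.58, "AG": -0.25, "AT": -0.59,
        "CA": 0.53, "CC": -0.22, "CG": 0.41, "CT": -0.25,
        "GA": 0.09, "GC": -0.38, "GG": -0.22, "GT": -0.58,
        "TA": 0.05, "TC": 0.09, "TG": 0.53, "TT": -0.08,
    },
    "rise": {
        "AA": 3.27, "AC": 3.36, "AG": 3.34, "AT": 3.31,
        "CA": 3.33, "CC": 3.42, "CG": 3.39, "CT": 3.34,
        "GA": 3.37, "GC": 3.40, "GG": 3.42, "GT": 3.36,
        "TA": 3.42, "TC": 3.37, "TG": 3.33, "TT": 3.27,
    },
}

#: Default histone methylation-category track names: 20 histone methylation
#: marks plus the variant H2A.Z, RNA polymerase II and CTCF (23 tracks,
#: giving 46 mean/sd features).
DEFAULT_METHYLATION_MARKS: tuple[str, ...] = (
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K9me1", "H3K9me2", "H3K9me3",
    "H3K27me1", "H3K27me2", "H3K27me3", "H3K36me1", "H3K36me3",
    "H3K79me1", "H3K79me2", "H3K79me3", "H4K20me1", "H4K20me3",
    "H2BK5me1", "H3R2me1", "H3R2me2", "H4R3me2",
    "H2A.Z", "PolII", "CTCF",
)

#: Default 18 histone acetylation marks (36 mean/sd features).
DEFAULT_ACETYLATION_MARKS: tuple[str, ...] = (
    "H2AK5ac", "H2AK9ac", "H2BK5ac", "H2BK12ac", "H2BK20ac", "H2BK120ac",
    "H3K4ac", "H3K9ac", "H3K14ac", "H3K18ac", "H3K23ac", "H3K27ac",
    "H3K36ac", "H4K5ac", "H4K8ac", "H4K12ac", "H4K16ac", "H4K91ac",
)

#: Default number of conserved-TFBS function-similarity groups.
DEFAULT_N_TFBS_GROUPS = 115

FEATURE_MATRIX_SIG_DIGITS = 12


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when a record is well-formed but violates a domain invariant."""


class UndefinedValueError(ValueError):
    """Raised when a statistic is undefined for the given input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence over {A,C,G,T,N}, uppercased on load."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("contig name must be non-empty")
        if len(self.sequence) == 0:
            raise ValidationError(f"contig {self.name!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(
                f"contig {self.name!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CpGCall:
    """One per-sample bisulfite methylation intensity at a CpG site.

    ``position`` is the 0-based coordinate of the C of the CpG dinucleotide
    on the forward strand.  ``intensity`` is percent methylation in [0, 100].
    """

    chrom: str
    position: int
    tissue: str
    sample: str
    intensity: float

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"negative CpG position {self.position}")
        if not (0.0 <= self.intensity <= 100.0):
            raise ValidationError(
                f"intensity {self.intensity} outside [0, 100] at "
                f"{self.chrom}:{self.position} ({self.tissue}/{self.sample})"
            )


class NumericTrack:
    """Step-function numeric signal with bedGraph semantics.

    Within each chromosome the steps are sorted and non-overlapping;
    positions not covered by any step have value 0 (tag counts are sparse,
    absence means zero tags).
    """

    def __init__(
        self,
        steps: Mapping[str, Sequence[tuple[int, int, float]]] | None = None,
    ) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        if steps:
            for chrom, chrom_steps in steps.items():
                self._set_chrom(chrom, chrom_steps)

    def _set_chrom(
        self, chrom: str, chrom_steps: Sequence[tuple[int, int, float]]
    ) -> None:
        if len(chrom_steps) == 0:
            return
        arr = sorted(chrom_steps)
        starts = np.asarray([s for s, _, _ in arr], dtype=np.int64)
        ends = np.asarray([e for _, e, _ in arr], dtype=np.int64)
        values = np.asarray([v for _, _, v in arr], dtype=float)
        if np.any(starts >= ends):
            raise FormatError(f"track {chrom}: step with start >= end")
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"track {chrom}: overlapping steps")
        self._starts[chrom] = starts
        self._ends[chrom] = ends
        self._values[chrom] = values

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def steps(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._starts:
            return []
        return list(
            zip(
                self._starts[chrom].tolist(),
                self._ends[chrom].tolist(),
                self._values[chrom].tolist(),
            )
        )

    def value_at(self, chrom: str, position: int) -> float:
        """Value at a single position; 0 if uncovered."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0.0
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i >= 0 and position < self._ends[chrom][i]:
            return float(self._values[chrom][i])
        return 0.0

    def interval_moments(
        self, chrom: str, start: int, end: int
    ) -> tuple[float, float]:
        """Per-nucleotide (mean, population sd) of the signal over [start, end).

        Uncovered positions contribute value 0.  Exact for step functions:
        each overlapping step contributes its value weighted by the length
        of the overlap.
        """
        if start >= end:
            raise ValueError("empty interval")
        length = end - start
        starts = self._starts.get(chrom)
        if starts is None:
            return 0.0, 0.0
        ends = self._ends[chrom]
        values = self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0, 0.0
        ov = (
            np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ).astype(float)
        v = values[lo:hi]
        total = float(np.sum(v * ov))
        total_sq = float(np.sum(v * v * ov))
        mean = total / length
        var = max(total_sq / length - mean * mean, 0.0)
        return mean, float(np.sqrt(var))


@dataclass
class TrackManifest:
    """All annotation resources the feature extractor reads.

    Under the defaults this yields the canonical 841-column feature space:
    115 TFBS groups (230 features), one conserved-element collection (2),
    23 histone-methylation tracks (46), 18 acetylation tracks (36), two
    nucleosome tracks (4), a gene table plus two cancer-process gene sets
    (2), and six dinucleotide conformational tables (6).
    """

    tfbs_groups: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    conserved_elements: list[GenomicInterval] = field(default_factory=list)
    histone_methylation_tracks: dict[str, NumericTrack] = field(
        default_factory=dict
    )
    histone_acetylation_tracks: dict[str, NumericTrack] = field(
        default_factory=dict
    )
    nucleosome_nt_track: NumericTrack = field(default_factory=NumericTrack)
    nucleosome_fragment_track: NumericTrack = field(default_factory=NumericTrack)
    repeats: list[GenomicInterval] = field(default_factory=list)
    genes: list[tuple[str, str, int, str]] = field(default_factory=list)
    oncogene_process_genes: set[str] = field(default_factory=set)
    tsg_process_genes: set[str] = field(default_factory=set)
    dinucleotide_property_tables: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_DINUCLEOTIDE_PROPERTIES.items()
        }
    )
    assembly: str = "synthetic"

    def __post_init__(self) -> None:
        for prop, table in self.dinucleotide_property_tables.items():
            if len(table) != 16:
                raise ValidationError(
                    f"dinucleotide table {prop!r} has {len(table)} entries, "
                    "expected 16"
                )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrackManifest":
        """Load a manifest YAML; relative paths resolve against its directory."""
        base = os.path.dirname(os.path.abspath(path))
        with open(path) as fh:
            doc = yaml.safe_load(fh)

        def _resolve(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base, p)

        tfbs_doc = doc["tfbs"]
        sites = read_bed(_resolve(tfbs_doc["file"]), scored=True)
        groups: dict[str, list[GenomicInterval]] = {
            g: [] for g in tfbs_doc["groups"]
        }
        for site in sites:
            if site.name not in groups:
                raise FormatError(
                    f"TFBS site group {site.name!r} not declared in manifest"
                )
            groups[site.name].append(site)

        meth = {
            mark: read_bedgraph(_resolve(p))
            for mark, p in doc["histone_methylation"].items()
        }
        acet = {
            mark: read_bedgraph(_resolve(p))
            for mark, p in doc["histone_acetylation"].items()
        }

        genes_df = pd.read_csv(_resolve(doc["genes"]), sep="\t")
        genes = [
            (str(r["name"]), str(r["chrom"]), int(r["tss"]), str(r["strand"]))
            for _, r in genes_df.iterrows()
        ]

        dinuc = read_dinucleotide_properties(
            _resolve(doc["dinucleotide_properties"])
        )
        return cls(
            tfbs_groups=groups,
            conserved_elements=read_bed(
                _resolve(doc["conserved_elements"]), scored=True
            ),
            histone_methylation_tracks=meth,
            histone_acetylation_tracks=acet,
            nucleosome_nt_track=read_bedgraph(
                _resolve(doc["nucleosome"]["nucleotide"])
            ),
            nucleosome_fragment_track=read_bedgraph(
                _resolve(doc["nucleosome"]["fragment"])
            ),
            repeats=read_bed(_resolve(doc["repeats"]), scored=False),
            genes=genes,
            oncogene_process_genes=read_gene_list(
                _resolve(doc["gene_sets"]["oncogene"])
            ),
            tsg_process_genes=read_gene_list(
                _resolve(doc["gene_sets"]["tumor_suppressor"])
            ),
            dinucleotide_property_tables=dinuc,
            assembly=str(doc.get("assembly", "synthetic")),
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a FASTA file into Contigs, uppercasing and mapping non-ACGTN to N.

    Raises :class:`FormatError` (with the offending line number) for records
    with no sequence or sequence before the first header.
    """
    # pre-scan for structural errors so the message can name a line
    with open(path) as fh:
        lines = fh.readlines()
    last_header_line = None
    has_seq_since_header = False
    saw_header = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if saw_header and not has_seq_since_header:
                raise FormatError(
                    f"{path}: empty FASTA record at line {last_header_line}"
                )
            if len(stripped) == 1:
                raise FormatError(
                    f"{path}: malformed FASTA header at line {lineno}"
                )
            saw_header = True
            last_header_line = lineno
            has_seq_since_header = False
        else:
            if not saw_header:
                raise FormatError(
                    f"{path}: sequence before first header at line {lineno}"
                )
            has_seq_since_header = True
    if not saw_header:
        raise FormatError(f"{path}: no FASTA records found")
    if not has_seq_since_header:
        raise FormatError(
            f"{path}: empty FASTA record at line {last_header_line}"
        )

    contigs = []
    for rec in SeqIO.parse(io.StringIO("".join(lines)), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in VALID_BASES else "N" for c in seq)
        n_replaced = sum(1 for a, b in zip(seq, cleaned) if a != b)
        if n_replaced:
            logger.warning(
                "contig %s: %d non-ACGTN characters mapped to N",
                rec.id, n_replaced,
            )
        contigs.append(Contig(name=rec.id, sequence=cleaned))
    return contigs


def read_bed(path: str | os.PathLike, scored: bool = False) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; score parsed from column 5 if ``scored``."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = None
            if scored:
                if len(cols) < 5:
                    raise FormatError(
                        f"{path}:{lineno}: scored BED needs >= 5 columns"
                    )
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric score {cols[4]!r}"
                    ) from exc
            strand = cols[5] if len(cols) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(
                        chrom=cols[0], start=start, end=end,
                        strand=strand, name=name, score=score,
                    )
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def read_bedgraph(path: str | os.PathLike) -> NumericTrack:
    """Read a 4-column bedGraph into a NumericTrack (overlaps are an error)."""
    steps: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            steps.setdefault(cols[0], []).append((start, end, value))
    try:
        return NumericTrack(steps)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: NumericTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for start, end, value in track.steps(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


CPG_CALL_COLUMNS = ("chrom", "position", "tissue", "sample", "intensity")


def read_cpg_calls(path: str | os.PathLike) -> list[CpGCall]:
    """Read a per-CpG methylation call TSV.

    Columns: chrom, position, tissue, sample, intensity.  Intensities
    outside [0, 100] and duplicate (chrom, position, tissue, sample) rows
    are validation errors, not silently repaired.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tissue": str,
                                            "sample": str})
    missing = [c for c in CPG_CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dup_mask = df.duplicated(
        subset=["chrom", "position", "tissue", "sample"], keep=False
    )
    if dup_mask.any():
        dups = (
            df.loc[dup_mask, ["chrom", "position", "tissue", "sample"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValidationError(f"{path}: duplicate call rows: {dups[:10]}")
    calls = []
    for row in df.itertuples(index=False):
        try:
            calls.append(
                CpGCall(
                    chrom=row.chrom, position=int(row.position),
                    tissue=row.tissue, sample=row.sample,
                    intensity=float(row.intensity),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return calls


def write_cpg_calls(calls: Iterable[CpGCall], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CPG_CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.position}\t{c.tissue}\t{c.sample}\t"
                f"{c.intensity:.6g}\n"
            )


def read_gene_list(path: str | os.PathLike) -> set[str]:
    """Read a plain-text gene list, one name per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


DINUC_PROPERTY_NAMES = ("twist", "tilt", "roll", "shift", "slide", "rise")


def read_dinucleotide_properties(
    path: str | os.PathLike,
) -> dict[str, dict[str, float]]:
    """Read the six dinucleotide conformational tables from TSV.

    Layout: header ``dinucleotide  twist  tilt  roll  shift  slide  rise``,
    one row per dinucleotide (16 rows required).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DINUC_PROPERTY_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing property columns {missing}")
    tables: dict[str, dict[str, float]] = {p: {} for p in DINUC_PROPERTY_NAMES}
    for row in df.itertuples(index=False):
        d = str(row.dinucleotide).upper()
        for p in DINUC_PROPERTY_NAMES:
            tables[p][d] = float(getattr(row, p))
    for p, table in tables.items():
        if len(table) != 16:
            raise FormatError(
                f"{path}: table {p!r} has {len(table)} dinucleotides, need 16"
            )
    return tables


def write_dinucleotide_properties(
    tables: Mapping[str, Mapping[str, float]], path: str | os.PathLike
) -> None:
    dinucs = sorted(tables[DINUC_PROPERTY_NAMES[0]])
    with open(path, "w") as fh:
        fh.write(
            "# representative B-DNA helical step parameters (synthetic "
            "defaults; edit to substitute a published table)\n"
        )
        fh.write("dinucleotide\t" + "\t".join(DINUC_PROPERTY_NAMES) + "\n")
        for d in dinucs:
            vals = "\t".join(f"{tables[p][d]:.6g}" for p in DINUC_PROPERTY_NAMES)
            fh.write(f"{d}\t{vals}\n")


# ---------------------------------------------------------------------------
# Feature-matrix round trip
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix: "FeatureMatrix", path: str | os.PathLike) -> None:
    """Write a feature matrix as TSV.

    The first line is a ``#categories:`` comment carrying the per-column
    category labels; values are printed to 12 significant digits so the
    write->read round trip is lossless at that precision.
    """
    from .feature_extractor import FeatureMatrix  # local: avoid import cycle

    assert isinstance(matrix, FeatureMatrix)
    with open(path, "w") as fh:
        fh.write(
            "#categories:\t"
            + "\t".join(matrix.categories[c] for c in matrix.data.columns)
            + "\n"
        )
        fh.write("island_id\t" + "\t".join(matrix.data.columns) + "\n")
        for island_id, row in matrix.data.iterrows():
            vals = "\t".join(
                f"{v:.{FEATURE_MATRIX_SIG_DIGITS}g}" for v in row.to_numpy()
            )
            fh.write(f"{island_id}\t{vals}\n")


def read_feature_matrix(path: str | os.PathLike) -> "FeatureMatrix":
    from .feature_extractor import FeatureMatrix

    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#categories:"):
            raise FormatError(f"{path}: missing #categories header line")
        cats = first.split("\t")[1:]
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "island_id":
            raise FormatError(f"{path}: missing island_id column header")
        names = header[1:]
        if len(cats) != len(names):
            raise FormatError(
                f"{path}: {len(cats)} category labels for {len(names)} columns"
            )
        ids = []
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(names) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(names) + 1} columns, "
                    f"got {len(cols)}"
                )
            ids.append(cols[0])
            rows.append([float(x) for x in cols[1:]])
    data = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(ids), len(names)),
        index=pd.Index(ids, name="island_id"),
        columns=names,
    )
    return FeatureMatrix(data=data, categories=dict(zip(names, cats)))
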