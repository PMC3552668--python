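"""Per-island feature extraction: the nine feature families.

For each CpG island the extractor computes

* general attributes — length, GC content, observed/expected CpG ratio (3);
* DNA composition — overlapping tetramer frequencies and their
  maximal-order Markov-model z-scores (256 + 256).  For a tetramer
  w = N1N2N3N4 with overlapping occurrence counts O(.),

      E(w)     = O(N1N2N3) * O(N2N3N4) / O(N2N3)
      sigma(w) = sqrt( E(w) * [O(N2N3)-O(N1N2N3)] * [O(N2N3)-O(N2N3N4)]
                       / O(N2N3)^2 )
      Z(w)     = (O(w) - E(w)) / sigma(w)

  i.e. the expected count under the maximal-order (second-order) Markov
  model implied by the word's two flanking trimers and shared dimer;
* conserved TFBS groups — per group, the count of sites overlapping the
  island plus flanks and their average conservation score (115 x 2 = 230);
* conserved elements — same pair for the single element collection (2);
* DNA conformation — island averages of six dinucleotide step parameters:
  twist, tilt, roll, shift, slide, rise (6);
* nucleosome positioning — mean/sd of per-nucleotide occupancy probability
  and mean/sd of the 147-bp fragment positioning potential over all
  fragments overlapping the island (4);
* gene function — binary indicators for an overlapping promoter
  (TSS-1000 .. TSS+200, strand-aware) of a gene in the oncogene-related or
  tumor-suppressor-related process gene sets (2);
* histone methylation / acetylation — mean and population sd of the ChIP
  tag count per nucleotide over the island, per mark (23 x 2 = 46 and
  18 x 2 = 36).

Under the default manifest this totals 841 features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import NumericTrack, TrackManifest, Contig, GenomicInterval
from .island_finder import CpGIsland, general_attributes

NUCLEOSOME_FRAGMENT_BP = 147
DEFAULT_FLANK_BP = 500
DEFAULT_Z_CAP = 10.0

CATEGORY_ORDER = (
    "general",
    "tetramer_freq",
    "tetramer_z",
    "tfbs",
    "conserved_element",
    "conformation",
    "nucleosome",
    "gene_function",
    "histone_methylation",
    "histone_acetylation",
)

BASES = "ACGT"
TETRAMERS = tuple("".join(p) for p in itertools.product(BASES, repeat=4))
_BASE_CODE = {ord(b): i for i, b in enumerate(BASES)}


@dataclass
class FeatureMatrix:
    """Islands x features with a category label per column."""

    data: pd.DataFrame
    categories: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.categories]
        if missing:
            raise ValueError(f"columns without category labels: {missing[:5]}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in columns {bad[:5]}")

    @property
    def island_ids(self) -> list[str]:
        return list(self.data.index)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in CATEGORY_ORDER}
        for col in self.data.columns:
            counts[self.categories[col]] += 1
        return counts

    def columns_in(self, categories: set[str] | Sequence[str]) -> list[str]:
        cats = set(categories)
        return [c for c in self.data.columns if self.categories[c] in cats]

    def drop_categories(self, categories: set[str]) -> "FeatureMatrix":
        keep = [c for c in self.data.columns if self.categories[c] not in categories]
        return FeatureMatrix(
            data=self.data[keep].copy(),
            categories={c: self.categories[c] for c in keep},
        )

    def subset_rows(self, island_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            data=self.data.loc[list(island_ids)].copy(),
            categories=dict(self.categories),
        )


# ---------------------------------------------------------------------------
# DNA composition: word counts and tetramer z-scores
# ---------------------------------------------------------------------------

@dataclass
class WordCounts:
    """Overlapping occurrence counts of words of lengths 2, 3, 4.

    Windows containing a non-ACGT character are skipped and excluded from
    the valid-window totals.
    """

    counts: dict[int, dict[str, int]] = field(default_factory=dict)
    valid_windows: dict[int, int] = field(default_factory=dict)

    def count(self, word: str) -> int:
        return self.counts[len(word)].get(word, 0)


def word_counts(seq: str) -> WordCounts:
    """Count all overlapping 2-, 3- and 4-mers of ``seq``."""
    if len(seq) < 4:
        raise ValueError(f"sequence of length {len(seq)} < 4")
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc = np.full(len(codes), -1, dtype=np.int64)
    for byte, code in _BASE_CODE.items():
        enc[codes == byte] = code
    valid = enc >= 0

    wc = WordCounts()
    for k in (2, 3, 4):
        n_win = len(seq) - k + 1
        idx = np.zeros(n_win, dtype=np.int64)
        ok = np.ones(n_win, dtype=bool)
        for j in range(k):
            idx = idx * 4 + np.where(valid[j:j + n_win], enc[j:j + n_win], 0)
            ok &= valid[j:j + n_win]
        counts = np.bincount(idx[ok], minlength=4 ** k)
        words: dict[str, int] = {}
        nz = np.flatnonzero(counts)
        for code in nz:
            word = _decode(int(code), k)
            words[word] = int(counts[code])
        wc.counts[k] = words
        wc.valid_windows[k] = int(ok.sum())
    return wc


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def tetramer_zscore(
    counts: WordCounts, tetramer: str, z_cap: float = DEFAULT_Z_CAP
) -> float:
    """Maximal-order Markov z-score of one tetramer from word counts.

    Degenerate cases: a zero shared-dimer count gives Z = 0; sigma = 0 with
    observed = expected gives Z = 0; sigma = 0 with observed != expected
    gives sign(O - E) * z_cap.
    """
    o_w = counts.count(tetramer)
    o_left = counts.count(tetramer[:3])
    o_right = counts.count(tetramer[1:])
    o_mid = counts.count(tetramer[1:3])
    if o_mid == 0:
        return 0.0
    expected = o_left * o_right / o_mid
    var = expected * (o_mid - o_left) * (o_mid - o_right) / (o_mid * o_mid)
    if var <= 0.0:
        if o_w == expected:
            return 0.0
        return z_cap if o_w > expected else -z_cap
    return float((o_w - expected) / np.sqrt(var))


def tetramer_features(seq: str, z_cap: float = DEFAULT_Z_CAP) -> dict[str, float]:
    """The 512 composition features: 256 frequencies + 256 z-scores.

    Frequencies are counts over valid 4-windows (summing to 1 whenever at
    least one window is valid).
    """
    counts = word_counts(seq)
    n_windows = counts.valid_windows[4]
    out: dict[str, float] = {}
    for t in TETRAMERS:
        out[f"freq_{t}"] = counts.count(t) / n_windows if n_windows else 0.0
    for t in TETRAMERS:
        out[f"z_{t}"] = tetramer_zscore(counts, t, z_cap=z_cap)
    return out


# ---------------------------------------------------------------------------
# Interval-overlap features
# ---------------------------------------------------------------------------

def _flank_window(
    island: CpGIsland, flank_bp: int, contig_length: int
) -> tuple[str, int, int]:
    iv = island.interval
    return iv.chrom, max(0, iv.start - flank_bp), min(contig_length, iv.end + flank_bp)


def _count_and_avgscore(
    sites: Sequence[GenomicInterval], chrom: str, start: int, end: int
) -> tuple[float, float]:
    scores = [
        (s.score if s.score is not None else 0.0)
        for s in sites
        if s.chrom == chrom and s.start < end and start < s.end
    ]
    if not scores:
        return 0.0, 0.0
    return float(len(scores)), float(np.mean(scores))


def tfbs_features(
    island: CpGIsland,
    flank_bp: int,
    manifest: TrackManifest,
    contig_length: int,
) -> dict[str, float]:
    """Per conserved-TFBS group: overlap count and mean conservation score."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if not manifest.tfbs_groups:
        raise ValueError("manifest declares no TFBS groups")
    chrom, start, end = _flank_window(island, flank_bp, contig_length)
    out: dict[str, float] = {}
    for group, sites in manifest.tfbs_groups.items():
        count, avg = _count_and_avgscore(sites, chrom, start, end)
        out[f"tfbs_{group}_count"] = count
        out[f"tfbs_{group}_avgscore"] = avg
    return out


def conserved_element_features(
    island: CpGIsland,
    flank_bp: int,
    manifest: TrackManifest,
    contig_length: int,
) -> dict[str, float]:
    """Count and mean score of conserved elements over island plus flanks."""
    chrom, start, end = _flank_window(island, flank_bp, contig_length)
    count, avg = _count_and_avgscore(
        manifest.conserved_elements, chrom, start, end
    )
    return {"conserved_element_count": count, "conserved_element_avgscore": avg}


# ---------------------------------------------------------------------------
# Structural, functional and chromatin features
# ---------------------------------------------------------------------------

def conformation_features(
    seq: str, tables: Mapping[str, Mapping[str, float]]
) -> dict[str, float]:
    """Island averages of the six dinucleotide conformational parameters."""
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 bp")
    dinucs = [seq[i:i + 2] for i in range(len(seq) - 1)]
    dinucs = [d for d in dinucs if "N" not in d]
    if not dinucs:
        raise ValueError("no valid dinucleotides (all contain N)")
    out = {}
    for prop, table in tables.items():
        out[f"conformation_{prop}"] = float(np.mean([table[d] for d in dinucs]))
    return out


def nucleosome_features(
    island: CpGIsland, manifest: TrackManifest
) -> dict[str, float]:
    """Nucleotide-level occupancy and 147-bp fragment-potential summaries.

    The fragment track stores at position s the positioning potential of
    the fragment [s, s+147); fragments overlapping the island are those
    with s in [start-146, end), clipped at the contig origin.
    """
    iv = island.interval
    nt_mean, nt_sd = manifest.nucleosome_nt_track.interval_moments(
        iv.chrom, iv.start, iv.end
    )
    frag_start = max(0, iv.start - (NUCLEOSOME_FRAGMENT_BP - 1))
    frag_mean, frag_sd = manifest.nucleosome_fragment_track.interval_moments(
        iv.chrom, frag_start, iv.end
    )
    return {
        "nucleosome_nt_mean": nt_mean,
        "nucleosome_nt_sd": nt_sd,
        "nucleosome_frag_mean": frag_mean,
        "nucleosome_frag_sd": frag_sd,
    }


def gene_function_features(
    island: CpGIsland, manifest: TrackManifest
) -> dict[str, float]:
    """Binary cancer-process indicators of genes with overlapping promoters.

    The promoter of a + strand gene is [TSS-1000, TSS+200); of a - strand
    gene [TSS-200, TSS+1000).  The oncogene feature is 1 iff some gene whose
    promoter overlaps the island belongs to the oncogene-related process
    set; the tumor-suppressor feature analogously.
    """
    iv = island.interval
    onco = 0.0
    tsg = 0.0
    for name, chrom, tss, strand in manifest.genes:
        if chrom != iv.chrom:
            continue
        if strand == "+":
            p_start, p_end = tss - 1000, tss + 200
        else:
            p_start, p_end = tss - 200, tss + 1000
        if p_start < iv.end and iv.start < p_end:
            if name in manifest.oncogene_process_genes:
                onco = 1.0
            if name in manifest.tsg_process_genes:
                tsg = 1.0
    return {"gene_function_oncogene": onco, "gene_function_tsg": tsg}


def histone_features(
    island: CpGIsland, tracks: Mapping[str, NumericTrack], prefix: str
) -> dict[str, float]:
    """Per mark: mean and population sd of tag counts over island nucleotides."""
    if not tracks:
        raise ValueError("no histone tracks supplied")
    iv = island.interval
    out = {}
    for mark, track in tracks.items():
        mean, sd = track.interval_moments(iv.chrom, iv.start, iv.end)
        out[f"{prefix}_{mark}_mean"] = mean
        out[f"{prefix}_{mark}_sd"] = sd
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_features(
    island: CpGIsland,
    genome: Mapping[str, Contig],
    manifest: TrackManifest,
    flank_bp: int = DEFAULT_FLANK_BP,
    z_cap: float = DEFAULT_Z_CAP,
) -> dict[str, tuple[str, float]]:
    """Feature name -> (category, value) for one island."""
    iv = island.interval
    contig = genome[iv.chrom]
    seq = contig.sequence[iv.start:iv.end]

    out: dict[str, tuple[str, float]] = {}
    for name, value in general_attributes(island, genome).items():
        out[name] = ("general", value)
    for name, value in tetramer_features(seq, z_cap=z_cap).items():
        cat = "tetramer_freq" if name.startswith("freq_") else "tetramer_z"
        out[name] = (cat, value)
    for name, value in tfbs_features(island, flank_bp, manifest, len(contig)).items():
        out[name] = ("tfbs", value)
    for name, value in conserved_element_features(
        island, flank_bp, manifest, len(contig)
    ).items():
        out[name] = ("conserved_element", value)
    for name, value in conformation_features(
        seq, manifest.dinucleotide_property_tables
    ).items():
        out[name] = ("conformation", value)
    for name, value in nucleosome_features(island, manifest).items():
        out[name] = ("nucleosome", value)
    for name, value in gene_function_features(island, manifest).items():
        out[name] = ("gene_function", value)
    for name, value in histone_features(
        island, manifest.histone_methylation_tracks, "hm"
    ).items():
        out[name] = ("histone_methylation", value)
    for name, value in histone_features(
        island, manifest.histone_acetylation_tracks, "ha"
    ).items():
        out[name] = ("histone_acetylation", value)
    return out


def feature_columns(manifest: TrackManifest) -> tuple[list[str], dict[str, str]]:
    """Deterministic column order and category labels for a manifest.

    Category blocks follow :data:`CATEGORY_ORDER`; tetramers are
    lexicographic; TFBS groups and histone marks follow manifest order.
    """
    names: list[str] = ["length", "gc_content", "obs_exp_cpg"]
    cats: dict[str, str] = {n: "general" for n in names}
    for t in TETRAMERS:
        names.append(f"freq_{t}")
        cats[f"freq_{t}"] = "tetramer_freq"
    for t in TETRAMERS:
        names.append(f"z_{t}")
        cats[f"z_{t}"] = "tetramer_z"
    for group in manifest.tfbs_groups:
        for suffix in ("count", "avgscore"):
            n = f"tfbs_{group}_{suffix}"
            names.append(n)
            cats[n] = "tfbs"
    for n in ("conserved_element_count", "conserved_element_avgscore"):
        names.append(n)
        cats[n] = "conserved_element"
    for prop in manifest.dinucleotide_property_tables:
        n = f"conformation_{prop}"
        names.append(n)
        cats[n] = "conformation"
    for n in (
        "nucleosome_nt_mean", "nucleosome_nt_sd",
        "nucleosome_frag_mean", "nucleosome_frag_sd",
    ):
        names.append(n)
        cats[n] = "nucleosome"
    for n in ("gene_function_oncogene", "gene_function_tsg"):
        names.append(n)
        cats[n] = "gene_function"
    for mark in manifest.histone_methylation_tracks:
        for suffix in ("mean", "sd"):
            n = f"hm_{mark}_{suffix}"
            names.append(n)
            cats[n] = "histone_methylation"
    for mark in manifest.histone_acetylation_tracks:
        for suffix in ("mean", "sd"):
            n = f"ha_{mark}_{suffix}"
            names.append(n)
            cats[n] = "histone_acetylation"
    return names, cats


def extract_all(
    islands: Sequence[CpGIsland],
    genome: Mapping[str, Contig],
    manifest: TrackManifest,
    flank_bp: int = DEFAULT_FLANK_BP,
    z_cap: float = DEFAULT_Z_CAP,
) -> FeatureMatrix:
    """Full feature matrix for a set of islands.

    With the default manifest (115 TFBS groups, 23 methylation and 18
    acetylation tracks) the matrix has exactly 841 columns.
    """
    names, cats = feature_columns(manifest)
    rows = np.empty((len(islands), len(names)), dtype=float)
    ids = []
    for i, island in enumerate(islands):
        try:
            feats = extract_features(
                island, genome, manifest, flank_bp=flank_bp, z_cap=z_cap
            )
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for island {island.id}: {exc}"
            ) from exc
        if set(feats) != set(names):
            raise RuntimeError(
                f"island {island.id}: feature names inconsistent with manifest"
            )
        rows[i] = [feats[n][1] for n in names]
        ids.append(island.id)
    data = pd.DataFrame(
        rows.reshape(len(islands), len(names)),
        index=pd.Index(ids, name="island_id"),
        columns=names,
    )
    return FeatureMatrix(data=data, categories=cats)
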