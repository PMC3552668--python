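"""Synthetic input bundles: genome, tracks, calls, gene sets, ground truth.

The generator emulates the structure of a bisulfite methylation study on a
small synthetic genome: CpG islands (satisfying the Gardiner-Garden
criteria by construction) embedded in AT-rich background, per-CpG
methylation calls for several tissues and samples with a bimodal
island-intensity distribution, histone/nucleosome/TFBS tracks whose levels
differ between methylated and unmethylated islands by configurable effect
sizes, and one designated divergent tissue whose labels flip more often
(emulating the germline's epigenetic distance from somatic tissues).  A
truth table records every latent variable so downstream recovery can be
checked exactly.

Everything is a pure function of the seed: the same spec produces a
byte-identical bundle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import genomic_io as gio
from .genomic_io import (
    Contig,
    DEFAULT_ACETYLATION_MARKS,
    DEFAULT_METHYLATION_MARKS,
    DEFAULT_N_TFBS_GROUPS,
)
from .island_finder import cpg_positions, find_islands, gc_content, obs_exp_cpg
from .label_builder import build_dataset, intensity_to_label

DEFAULT_TISSUES = (
    "CD4", "CD8", "liver", "heart_muscle", "skeletal_muscle",
    "fetal_skeletal_muscle", "fetal_liver", "placenta",
    "dermal_melanocytes", "dermal_fibroblasts", "dermal_keratinocytes",
    "sperm",
)

#: Resampling margin around the 10/50 label cutoffs: island intensities are
#: redrawn when they land within this distance of a cutoff, so island-level
#: labels are recoverable exactly from noisy calls.
LABEL_MARGIN = 1.5
CALL_NOISE_HALF_WIDTH = 3.0


class SpecError(ValueError):
    """Raised when a simulation spec is infeasible before generation."""


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study; the seed fixes every output."""

    seed: int = 0
    n_islands: int = 469
    island_length_range: tuple[int, int] = (300, 800)
    background_gc: float = 0.05
    island_gc: float = 0.56
    n_tissues: int = 12
    class_balance: float = 101 / 469  # fraction methylated, CD4-like
    intensity_means: tuple[float, float] = (3.0, 92.0)  # unmeth, meth
    intensity_sd: float = 6.0
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "histone_methylation": 3.0,
            "histone_acetylation": 3.0,
            "nucleosome": 0.0,
            "tfbs": 0.0,
        }
    )
    call_coverage: float = 0.8
    samples_per_tissue: int = 3
    sperm_like_divergence: float = 0.08
    somatic_divergence: float = 0.01
    n_tfbs_groups: int = DEFAULT_N_TFBS_GROUPS
    tfbs_base_rate: float = 0.15
    n_genes_per_island: float = 0.3
    buffer_bp: int = 500
    gap_range: tuple[int, int] = (200, 600)

    def validate(self) -> None:
        probs = [
            self.background_gc, self.island_gc, self.class_balance,
            self.call_coverage, self.sperm_like_divergence,
            self.somatic_divergence,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise SpecError("probabilities must lie in [0, 1]")
        if self.island_gc < 0.55:
            raise SpecError(
                f"island GC {self.island_gc} too close to the 0.5 criterion; "
                "islands could not satisfy the detection thresholds robustly"
            )
        if self.n_islands < 1 or self.n_tissues < 1:
            raise SpecError("need at least one island and one tissue")
        if self.samples_per_tissue < 1:
            raise SpecError("need at least one sample per tissue")
        if not all(np.isfinite(v) for v in self.effect_sizes.values()):
            raise SpecError("effect sizes must be finite")
        lo, hi = self.island_length_range
        if lo < 200 or hi < lo:
            raise SpecError("island lengths must be >= 200 and ordered")

    @property
    def tissues(self) -> list[str]:
        if self.n_tissues <= len(DEFAULT_TISSUES):
            names = list(DEFAULT_TISSUES[: self.n_tissues])
            if self.n_tissues == len(DEFAULT_TISSUES):
                return names
            # keep the divergent tissue last whenever there are >= 2 tissues
            if self.n_tissues >= 2:
                names[-1] = "sperm"
            return names
        names = list(DEFAULT_TISSUES)
        names += [f"tissue_{i}" for i in range(len(DEFAULT_TISSUES), self.n_tissues)]
        return names

    @property
    def divergent_tissue(self) -> str | None:
        return self.tissues[-1] if self.n_tissues >= 2 else None


@dataclass
class Bundle:
    """Paths of a generated input bundle."""

    root: str

    @property
    def fasta(self) -> str:
        return os.path.join(self.root, "genome.fa")

    @property
    def islands_bed(self) -> str:
        return os.path.join(self.root, "islands.bed")

    @property
    def repeats_bed(self) -> str:
        return os.path.join(self.root, "repeats.bed")

    @property
    def calls_tsv(self) -> str:
        return os.path.join(self.root, "calls.tsv")

    @property
    def manifest_yaml(self) -> str:
        return os.path.join(self.root, "manifest.yaml")

    @property
    def truth_tsv(self) -> str:
        return os.path.join(self.root, "truth.tsv")

    @property
    def spec_yaml(self) -> str:
        return os.path.join(self.root, "spec.yaml")

    def load_genome(self) -> dict[str, Contig]:
        return {c.name: c for c in gio.read_fasta(self.fasta)}

    def load_manifest(self) -> gio.TrackManifest:
        return gio.TrackManifest.load(self.manifest_yaml)

    def load_truth(self) -> pd.DataFrame:
        return pd.read_csv(self.truth_tsv, sep="\t")

    def load_planted_islands(self):
        from .island_finder import islands_from_bed

        return islands_from_bed(
            gio.read_bed(self.islands_bed), self.load_genome()
        )


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

_BASES_ARR = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES_ARR, size=length, p=p))


def _island_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """A CpG-enriched GC-rich island sequence, rejection-sampled so the
    whole stretch passes the detection criteria with margin.

    The accepted GC band is kept narrow and close to the 0.5 criterion so
    detected island boundaries stay sharp: the higher an island's GC, the
    further a detected region can extend into AT background before failing
    the criteria.
    """
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    gc_lo = max(0.55, gc - 0.02)
    gc_hi = gc + 0.03
    for _ in range(500):
        arr = rng.choice(_BASES_ARR, size=length, p=p)
        # plant extra non-overlapping CpG dinucleotides
        plant = np.flatnonzero(rng.random(length - 1) < 0.02)
        last = -2
        for q in plant:
            if q > last + 1:
                arr[q] = "C"
                arr[q + 1] = "G"
                last = q
        seq = "".join(arr)
        if gc_lo <= gc_content(seq) <= gc_hi and obs_exp_cpg(seq) >= 0.8:
            return seq
    raise SpecError("could not generate an island passing the criteria")


def _draw_intensity(
    rng: np.random.Generator, methylated: bool, spec: SimulationSpec
) -> float:
    """Beta-like bimodal intensity in [0, 100], kept clear of the label
    cutoffs by LABEL_MARGIN so labels are recoverable from noisy calls."""
    mean = spec.intensity_means[1 if methylated else 0] / 100.0
    sd = spec.intensity_sd / 100.0
    var = min(sd * sd, mean * (1 - mean) * 0.95)
    nu = mean * (1 - mean) / var - 1.0
    a, b = mean * nu, (1 - mean) * nu
    lo_cut, hi_cut = 10.0, 50.0
    for _ in range(1000):
        x = 100.0 * rng.beta(a, b)
        near_cut = (
            abs(x - lo_cut) < LABEL_MARGIN or abs(x - hi_cut) < LABEL_MARGIN
        )
        if not near_cut:
            return float(x)
    raise SpecError("intensity distribution concentrated on a label cutoff")


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate(spec: SimulationSpec, out_dir: str | os.PathLike) -> Bundle:
    """Generate the complete input bundle under ``out_dir``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    root = str(out_dir)
    os.makedirs(root, exist_ok=True)
    os.makedirs(os.path.join(root, "tracks"), exist_ok=True)
    os.makedirs(os.path.join(root, "gene_sets"), exist_ok=True)
    chrom = "chrS"

    # --- genome with embedded islands -------------------------------------
    lo, hi = spec.island_length_range
    pieces: list[str] = []
    island_coords: list[tuple[int, int]] = []
    pos = 0
    for _ in range(spec.n_islands):
        gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
        pre = _random_seq(rng, gap + spec.buffer_bp, spec.background_gc)
        pieces.append(pre)
        pos += len(pre)
        length = int(rng.integers(lo, hi + 1))
        isl = _island_seq(rng, length, spec.island_gc)
        island_coords.append((pos, pos + length))
        pieces.append(isl)
        pos += length
        post = _random_seq(rng, spec.buffer_bp, spec.background_gc)
        pieces.append(post)
        pos += len(post)

    # decoy repeats: GC-rich segments fully covered by the repeat mask
    repeat_coords: list[tuple[int, int]] = []
    for _ in range(3):
        gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
        pieces.append(_random_seq(rng, gap + spec.buffer_bp, spec.background_gc))
        pos = sum(len(p) for p in pieces)
        rep = _island_seq(rng, 400, spec.island_gc)
        repeat_coords.append((pos, pos + 400))
        pieces.append(rep)
        pieces.append(_random_seq(rng, spec.buffer_bp, spec.background_gc))
    genome_seq = "".join(pieces)

    with open(os.path.join(root, "genome.fa"), "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome_seq), 80):
            fh.write(genome_seq[i:i + 80] + "\n")

    with open(os.path.join(root, "repeats.bed"), "w") as fh:
        for start, end in repeat_coords:
            fh.write(f"{chrom}\t{start}\t{end}\trepeat\n")

    island_ids = [f"island_{i:05d}" for i in range(spec.n_islands)]
    with open(os.path.join(root, "islands.bed"), "w") as fh:
        for iid, (start, end) in zip(island_ids, island_coords):
            fh.write(f"{chrom}\t{start}\t{end}\t{iid}\n")

    # --- latent classes and per-tissue labels ------------------------------
    consensus = rng.random(spec.n_islands) < spec.class_balance
    tissues = spec.tissues
    divergent = spec.divergent_tissue
    tissue_class: dict[str, np.ndarray] = {}
    for t_i, tissue in enumerate(tissues):
        if t_i == 0:
            flips = np.zeros(spec.n_islands, dtype=bool)  # reference tissue
        else:
            p = (
                spec.sperm_like_divergence
                if tissue == divergent
                else spec.somatic_divergence
            )
            flips = rng.random(spec.n_islands) < p
        tissue_class[tissue] = consensus ^ flips

    tissue_intensity = {
        tissue: np.array(
            [
                _draw_intensity(rng, bool(c), spec)
                for c in tissue_class[tissue]
            ]
        )
        for tissue in tissues
    }

    # --- methylation calls -------------------------------------------------
    n_cpg_counts = np.zeros(spec.n_islands, dtype=int)
    sample_names = [f"s{j + 1}" for j in range(spec.samples_per_tissue)]
    island_sites = []
    for i, (start, end) in enumerate(island_coords):
        sites = cpg_positions(genome_seq[start:end], offset=start)
        island_sites.append(np.asarray(sites, dtype=int))
        n_cpg_counts[i] = len(sites)
    col_pos: list[np.ndarray] = []
    col_tissue: list[str] = []
    col_sample: list[str] = []
    col_val: list[np.ndarray] = []
    for tissue in tissues:
        for i, sites in enumerate(island_sites):
            n_cov = int(round(spec.call_coverage * len(sites)))
            chosen = np.sort(rng.choice(len(sites), size=n_cov, replace=False))
            base = tissue_intensity[tissue][i]
            noise = rng.uniform(
                -CALL_NOISE_HALF_WIDTH, CALL_NOISE_HALF_WIDTH,
                size=(len(sample_names), n_cov),
            )
            vals = np.clip(base + noise, 0.0, 100.0)
            for j, sample in enumerate(sample_names):
                col_pos.append(sites[chosen])
                col_tissue.extend([tissue] * n_cov)
                col_sample.extend([sample] * n_cov)
                col_val.append(vals[j])
    positions = (
        np.concatenate(col_pos) if col_pos else np.array([], dtype=int)
    )
    values = np.concatenate(col_val) if col_val else np.array([])
    calls_df = pd.DataFrame(
        {
            "chrom": chrom,
            "position": positions,
            "tissue": col_tissue,
            "sample": col_sample,
            "intensity": np.round(values, 4),
        }
    )
    calls_df.to_csv(
        os.path.join(root, "calls.tsv"), sep="\t", index=False,
        float_format="%.4f",
    )

    # --- chromatin and annotation tracks -----------------------------------
    es = spec.effect_sizes
    manifest_doc: dict = {"assembly": "synthetic"}

    def _mark_tracks(marks: tuple[str, ...], effect: float, prefix: str) -> dict:
        paths = {}
        for mark in marks:
            base_level = rng.uniform(1.0, 4.0)
            values = np.maximum(
                base_level
                + effect * consensus.astype(float)
                + rng.normal(0.0, 1.0, spec.n_islands),
                0.0,
            )
            fname = os.path.join("tracks", f"{prefix}_{mark}.bedgraph")
            with open(os.path.join(root, fname), "w") as fh:
                for (start, end), v in zip(island_coords, values):
                    mid = (start + end) // 2
                    fh.write(f"{chrom}\t{start}\t{mid}\t{v * 1.2:.6g}\n")
                    fh.write(f"{chrom}\t{mid}\t{end}\t{v * 0.8:.6g}\n")
            paths[mark] = fname
        return paths

    manifest_doc["histone_methylation"] = _mark_tracks(
        DEFAULT_METHYLATION_MARKS, es.get("histone_methylation", 0.0), "hm"
    )
    manifest_doc["histone_acetylation"] = _mark_tracks(
        DEFAULT_ACETYLATION_MARKS, es.get("histone_acetylation", 0.0), "ha"
    )

    nuc_effect = es.get("nucleosome", 0.0)
    occ = np.clip(
        0.4
        + 0.1 * nuc_effect * consensus.astype(float)
        + rng.normal(0.0, 0.1, spec.n_islands),
        0.0, 1.0,
    )
    pot = (
        1.0
        + 0.5 * nuc_effect * consensus.astype(float)
        + rng.normal(0.0, 0.5, spec.n_islands)
    )
    with open(os.path.join(root, "tracks", "nucleosome_nt.bedgraph"), "w") as fh:
        for (start, end), v in zip(island_coords, occ):
            mid = (start + end) // 2
            fh.write(f"{chrom}\t{start}\t{mid}\t{min(v * 1.1, 1.0):.6g}\n")
            fh.write(f"{chrom}\t{mid}\t{end}\t{v * 0.9:.6g}\n")
    with open(os.path.join(root, "tracks", "nucleosome_frag.bedgraph"), "w") as fh:
        for (start, end), v in zip(island_coords, pot):
            fh.write(f"{chrom}\t{max(0, start - 146)}\t{end}\t{v:.6g}\n")
    manifest_doc["nucleosome"] = {
        "nucleotide": os.path.join("tracks", "nucleosome_nt.bedgraph"),
        "fragment": os.path.join("tracks", "nucleosome_frag.bedgraph"),
    }

    # conserved TFBS: Poisson site counts per island window per group, rate
    # scaled by exp(es/2) for methylated islands
    groups = [f"G{g + 1:03d}" for g in range(spec.n_tfbs_groups)]
    tfbs_effect = es.get("tfbs", 0.0)
    with open(os.path.join(root, "tracks", "tfbs.bed"), "w") as fh:
        for g_name in groups:
            for i, (start, end) in enumerate(island_coords):
                rate = spec.tfbs_base_rate * float(
                    np.exp(0.5 * tfbs_effect * consensus[i])
                )
                for _ in range(rng.poisson(rate)):
                    s = int(rng.integers(max(0, start - 400), end + 400 - 10))
                    score = float(rng.uniform(200, 900))
                    fh.write(
                        f"{chrom}\t{s}\t{s + 10}\t{g_name}\t{score:.4g}\t+\n"
                    )
    manifest_doc["tfbs"] = {
        "file": os.path.join("tracks", "tfbs.bed"),
        "groups": groups,
    }

    with open(os.path.join(root, "tracks", "conserved_elements.bed"), "w") as fh:
        n_elements = max(10, spec.n_islands // 3)
        for _ in range(n_elements):
            s = int(rng.integers(0, len(genome_seq) - 50))
            score = float(rng.uniform(100, 700))
            fh.write(f"{chrom}\t{s}\t{s + 50}\telement\t{score:.4g}\t+\n")
    manifest_doc["conserved_elements"] = os.path.join(
        "tracks", "conserved_elements.bed"
    )

    # genes: TSSs near a random subset of islands
    n_genes = max(2, int(spec.n_genes_per_island * spec.n_islands))
    gene_rows = []
    with_gene = rng.choice(spec.n_islands, size=min(n_genes, spec.n_islands),
                           replace=False)
    for j, i in enumerate(sorted(with_gene)):
        start, end = island_coords[i]
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(start, end))
        gene_rows.append((f"GENE{j + 1:04d}", chrom, tss, strand))
    pd.DataFrame(
        gene_rows, columns=["name", "chrom", "tss", "strand"]
    ).to_csv(os.path.join(root, "genes.tsv"), sep="\t", index=False)
    manifest_doc["genes"] = "genes.tsv"

    gene_names = [g[0] for g in gene_rows]
    n_onco = max(1, len(gene_names) // 4)
    n_tsg = max(1, len(gene_names) // 5)
    onco = set(rng.choice(gene_names, size=n_onco, replace=False))
    tsg = set(rng.choice(gene_names, size=n_tsg, replace=False))
    gio.write_gene_list(onco, os.path.join(root, "gene_sets", "oncogene.txt"))
    gio.write_gene_list(tsg, os.path.join(root, "gene_sets", "tsg.txt"))
    manifest_doc["gene_sets"] = {
        "oncogene": os.path.join("gene_sets", "oncogene.txt"),
        "tumor_suppressor": os.path.join("gene_sets", "tsg.txt"),
    }

    gio.write_dinucleotide_properties(
        gio.DEFAULT_DINUCLEOTIDE_PROPERTIES,
        os.path.join(root, "dinucleotide_properties.tsv"),
    )
    manifest_doc["dinucleotide_properties"] = "dinucleotide_properties.tsv"
    manifest_doc["repeats"] = "repeats.bed"

    with open(os.path.join(root, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest_doc, fh, sort_keys=True)

    # --- truth table --------------------------------------------------------
    rows = []
    for tissue in tissues:
        for i, iid in enumerate(island_ids):
            start, end = island_coords[i]
            intensity = tissue_intensity[tissue][i]
            rows.append(
                {
                    "island_id": iid,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "tissue": tissue,
                    "consensus_methylated": int(consensus[i]),
                    "methylated": int(tissue_class[tissue][i]),
                    "intensity": round(float(intensity), 6),
                    "label": intensity_to_label(intensity),
                    "n_cpg": int(n_cpg_counts[i]),
                }
            )
    pd.DataFrame(rows).to_csv(
        os.path.join(root, "truth.tsv"), sep="\t", index=False
    )

    with open(os.path.join(root, "spec.yaml"), "w") as fh:
        doc = asdict(spec)
        doc["island_length_range"] = list(spec.island_length_range)
        doc["intensity_means"] = list(spec.intensity_means)
        doc["gap_range"] = list(spec.gap_range)
        yaml.safe_dump(doc, fh, sort_keys=True)

    return Bundle(root=root)


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

class VerificationError(AssertionError):
    """Raised when a bundle fails its self-consistency checks."""


def verify_bundle(
    bundle: Bundle,
    min_recovery: float = 0.95,
    min_reciprocal_overlap: float = 0.8,
) -> dict:
    """Self-consistency checks of a generated bundle.

    Re-runs island detection on the synthetic genome and requires at least
    ``min_recovery`` of the planted islands to be recovered with reciprocal
    overlap >= ``min_reciprocal_overlap``; rebuilds per-tissue labels from
    the calls and requires exact agreement with the truth table for every
    island passing the coverage filter.  Returns a report dict; raises
    :class:`VerificationError` with details on failure.
    """
    genome = bundle.load_genome()
    repeats = gio.read_bed(bundle.repeats_bed)
    planted = gio.read_bed(bundle.islands_bed)
    truth = bundle.load_truth()
    calls = gio.read_cpg_calls(bundle.calls_tsv)

    found = []
    for contig in genome.values():
        found.extend(find_islands(contig, repeats))

    recovered = 0
    misses = []
    for p in planted:
        ok = False
        for f in found:
            iv = f.interval
            if iv.chrom != p.chrom:
                continue
            ov = min(iv.end, p.end) - max(iv.start, p.start)
            if ov <= 0:
                continue
            if (
                ov / len(p) >= min_reciprocal_overlap
                and ov / len(iv) >= min_reciprocal_overlap
            ):
                ok = True
                break
        if ok:
            recovered += 1
        else:
            misses.append(p.name or f"{p.chrom}:{p.start}-{p.end}")
    recovery = recovered / len(planted)

    report: dict = {
        "n_planted": len(planted),
        "n_found": len(found),
        "recovery": recovery,
        "missed_islands": misses,
    }
    if recovery < min_recovery:
        raise VerificationError(
            f"island recovery {recovery:.3f} < {min_recovery}; "
            f"missed: {misses[:10]}"
        )

    planted_islands = bundle.load_planted_islands()
    tissues = truth["tissue"].unique()
    mismatches = []
    n_checked = 0
    n_dropped = 0
    for tissue in tissues:
        ds = build_dataset(str(tissue), planted_islands, calls, genome)
        expected = truth[truth["tissue"] == tissue].set_index("island_id")
        got = ds.records.set_index("island_id")
        n_dropped += len(expected) - len(got)
        for iid, row in got.iterrows():
            n_checked += 1
            if row["label"] != expected.loc[iid, "label"]:
                mismatches.append(
                    (str(tissue), iid, expected.loc[iid, "label"], row["label"])
                )
    report["n_label_checked"] = n_checked
    report["n_coverage_dropped"] = n_dropped
    report["label_mismatches"] = mismatches
    if n_checked and mismatches:
        raise VerificationError(
            f"{len(mismatches)} island labels differ from truth: "
            f"{mismatches[:10]}"
        )
    return report
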