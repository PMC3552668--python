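"""Island-level methylation intensities, binary labels and cross-tissue reports.

Per-CpG bisulfite intensities (0-100) are averaged over samples within a
tissue, then over the CpG dinucleotides of an island.  Islands with more
than 10% of their CpGs annotated are retained; islands with intensity >= 50
are labelled methylated (positive), <= 10 unmethylated (negative), and
anything in between is excluded from training.  Across tissues, an island
is differentially methylated in a tissue pair when its binary labels are
opposite; intermediate islands never count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import Contig, CpGCall
from .island_finder import CpGIsland, cpg_positions

LABEL_METHYLATED = "methylated"
LABEL_UNMETHYLATED = "unmethylated"
LABEL_EXCLUDED = "excluded"

METHYLATED_MIN_INTENSITY = 50.0
UNMETHYLATED_MAX_INTENSITY = 10.0
MIN_COVERAGE = 0.10


def intensity_to_label(
    intensity: float,
    methylated_min: float = METHYLATED_MIN_INTENSITY,
    unmethylated_max: float = UNMETHYLATED_MAX_INTENSITY,
) -> str:
    """Binary label from island intensity; boundaries are inclusive."""
    if intensity >= methylated_min:
        return LABEL_METHYLATED
    if intensity <= unmethylated_max:
        return LABEL_UNMETHYLATED
    return LABEL_EXCLUDED


@dataclass
class MethylationDataset:
    """Island-level intensities and labels for one tissue.

    ``records`` has columns island_id, intensity, coverage, label.  Records
    with the excluded label are retained but flagged; they are not used for
    training.  Every retained record has coverage > the 10% filter.
    """

    tissue: str
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"island_id", "intensity", "coverage", "label"}
        if len(self.records) and not required.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")

    @property
    def trainable(self) -> pd.DataFrame:
        """Records with a definite binary label."""
        return self.records[self.records["label"] != LABEL_EXCLUDED]

    def class_counts(self) -> dict[str, int]:
        return self.records["label"].value_counts().to_dict()


def cpg_intensity(intensities: Sequence[float]) -> float:
    """Per-site methylation intensity: mean over samples."""
    if len(intensities) == 0:
        raise ValueError("no calls for site")
    return float(np.mean(intensities))


def site_intensities(
    calls: Sequence[CpGCall], tissue: str
) -> dict[tuple[str, int], float]:
    """Average per-sample calls into per-site intensities for one tissue."""
    acc: dict[tuple[str, int], list[float]] = {}
    for c in calls:
        if c.tissue == tissue:
            acc.setdefault((c.chrom, c.position), []).append(c.intensity)
    return {site: cpg_intensity(v) for site, v in acc.items()}


def island_intensity(
    island: CpGIsland,
    genome: Mapping[str, Contig],
    sites: Mapping[tuple[str, int], float] | Mapping[int, float],
) -> tuple[float, float]:
    """(intensity, coverage) of an island from per-site intensities.

    Coverage is the fraction of the island's CpG dinucleotides carrying an
    intensity; the intensity is the mean over those annotated sites.  Keys
    of ``sites`` may be (chrom, position) or bare positions.
    """
    iv = island.interval
    contig = genome[iv.chrom]
    positions = cpg_positions(contig.sequence[iv.start:iv.end], offset=iv.start)
    if not positions:
        raise ValueError(
            f"island {island.id} has no CpG dinucleotides; cannot be a "
            "Gardiner-Garden island"
        )
    values = []
    for pos in positions:
        v = sites.get((iv.chrom, pos))
        if v is None:
            v = sites.get(pos)  # type: ignore[arg-type]
        if v is not None:
            values.append(v)
    coverage = len(values) / len(positions)
    intensity = float(np.mean(values)) if values else float("nan")
    return intensity, coverage


def build_dataset(
    tissue: str,
    islands: Sequence[CpGIsland],
    calls: Sequence[CpGCall],
    genome: Mapping[str, Contig],
    min_coverage: float = MIN_COVERAGE,
) -> MethylationDataset:
    """Label all sufficiently covered islands for one tissue.

    Islands whose annotated-CpG fraction is <= ``min_coverage`` are dropped;
    the rest get a label from their mean intensity (excluded labels are
    retained but flagged).
    """
    sites = site_intensities(calls, tissue)
    if not sites:
        raise ValueError(f"no calls for tissue {tissue!r}")
    rows = []
    for island in islands:
        intensity, coverage = island_intensity(island, genome, sites)
        if coverage <= min_coverage:
            continue
        rows.append(
            {
                "island_id": island.id,
                "intensity": intensity,
                "coverage": coverage,
                "label": intensity_to_label(intensity),
            }
        )
    records = pd.DataFrame(
        rows, columns=["island_id", "intensity", "coverage", "label"]
    )
    return MethylationDataset(tissue=tissue, records=records)


def cross_tissue_report(
    datasets: Sequence[MethylationDataset],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-pair counts and intensity correlations across tissues.

    The common set is the islands with a non-excluded label in every tissue.
    The differential count for a tissue pair is the number of common islands
    methylated in one tissue and unmethylated in the other (opposite binary
    labels).  The correlation matrix is Pearson over the intensities of the
    common islands.  Counts are symmetric with zero diagonal; correlations
    symmetric with unit diagonal.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two tissues")
    tissues = [d.tissue for d in datasets]
    if len(set(tissues)) != len(tissues):
        raise ValueError("duplicate tissue names")

    per_tissue = {}
    for d in datasets:
        tr = d.trainable.set_index("island_id")
        per_tissue[d.tissue] = tr
    common = set.intersection(*(set(t.index) for t in per_tissue.values()))
    if not common:
        raise ValueError("no islands with definite labels in every tissue")
    common_ids = sorted(common)

    labels = pd.DataFrame(
        {t: per_tissue[t].loc[common_ids, "label"] for t in tissues}
    )
    intensities = pd.DataFrame(
        {t: per_tissue[t].loc[common_ids, "intensity"] for t in tissues}
    )

    n = len(tissues)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels.iloc[:, i], labels.iloc[:, j]
            diff = int(
                (
                    ((a == LABEL_METHYLATED) & (b == LABEL_UNMETHYLATED))
                    | ((a == LABEL_UNMETHYLATED) & (b == LABEL_METHYLATED))
                ).sum()
            )
            counts[i, j] = counts[j, i] = diff
    count_df = pd.DataFrame(counts, index=tissues, columns=tissues)
    corr_df = intensities.corr(method="pearson")
    np.fill_diagonal(corr_df.values, 1.0)
    return count_df, corr_df


def write_labels(dataset: MethylationDataset, path: str) -> None:
    out = dataset.records.copy()
    out.insert(0, "tissue", dataset.tissue)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_labels(path: str) -> MethylationDataset:
    df = pd.read_csv(path, sep="\t")
    tissues = df["tissue"].unique()
    if len(tissues) != 1:
        raise ValueError(f"label file must hold one tissue, found {tissues}")
    return MethylationDataset(
        tissue=str(tissues[0]),
        records=df[["island_id", "intensity", "coverage", "label"]],
    )
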