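"""Published summary tables shipped with the package.

Small fixtures transcribed from the study's printed tables: the Nile
tilapia re-anchoring comparison, the per-map anchoring of the Lake
Malawi zebra-cichlid assembly (with the map selected per LG for the
final anchoring), the discordant-contig list behind the
inter-chromosomal comparison, and the RefSeq annotation-report counts
for the old and new zebra-cichlid assemblies.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# total p-contig assembly size of the zebra cichlid assembly (bp),
# as reported with the final anchoring total
MZEBRA_ASSEMBLY_BP = 957_200_631


def _load(name: str) -> pd.DataFrame:
    with resources.files("chromostruct.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def nile_tilapia_anchoring() -> pd.DataFrame:
    """Per-LG anchored bp of the previous and re-anchored tilapia assemblies."""
    return _load("nile_tilapia_anchoring.tsv")


def malawi_map_anchoring() -> pd.DataFrame:
    """Per-LG anchored bp for each of the four Lake Malawi maps and the final
    combined anchoring, with the map selected per LG."""
    return _load("malawi_map_anchoring.tsv")


def malawi_discordant_contigs() -> pd.DataFrame:
    """Long-format per-map LG assignments for the nine discordant contigs."""
    return _load("malawi_discordant_contigs.tsv")


def mzebra_annotation_counts() -> pd.DataFrame:
    """RefSeq annotation feature counts for the old and new assemblies."""
    return _load("mzebra_annotation_counts.tsv")


def discordant_assignment_inputs() -> tuple[dict, dict, dict]:
    """The discordant-contig table reshaped into the inputs of
    detect_interchromosomal_differences: per-map assignments, contig
    sizes, and repeat notes."""
    df = malawi_discordant_contigs()
    per_map: dict[str, dict[str, tuple[str, int]]] = {}
    sizes: dict[str, int] = {}
    notes: dict[str, str] = {}
    for row in df.itertuples(index=False):
        per_map.setdefault(row.map_id, {})[row.contig] = (row.lg, int(row.n_markers))
        sizes[row.contig] = int(row.size_bp)
        if isinstance(row.note, str) and row.note:
            notes[row.contig] = row.note
    return per_map, sizes, notes
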