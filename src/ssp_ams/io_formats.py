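"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain TSV with fixed, documented headers; writers
emit deterministic column and row order (sorted by id) so outputs are
byte-reproducible.  Readers are strict: booleans must be 0/1, required
numeric fields must parse and must not be NaN, and unknown or duplicate ids
raise rather than being silently coerced.

The unified prediction TSV is the contract for tool votes.  Best-effort
converters from a few raw tool output dialects (SignalP 5 short, TMHMM
short, Phobius short) are provided as a convenience only — tool output
formats drift between versions, so conversion should be inspected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ams_orthology import GenomeComparison, GroupClassification, SSPSource
from .coexpression import CoexpressionEdge, Rank, SSPRank
from .ssp_caller import SSPCall, SSPCategory
from .types import (
    AmsStatus,
    DERecord,
    Direction,
    Lineage,
    OrthologGroup,
    ProteinPrediction,
    SpeciesRecord,
)


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


PREDICTION_COLUMNS = [
    "protein_id",
    "species_id",
    "length_aa",
    "complete_orf",
    "nss_signalp",
    "nss_phobius",
    "nss_targetp",
    "tm_tmhmm",
    "tm_memsat",
    "tm_phobius",
    "loc_apoplastp",
    "loc_deeploc",
    "loc_msubp",
]

_BOOL_COLUMNS = PREDICTION_COLUMNS[3:]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def _parse_bool01(series: pd.Series, column: str, path) -> np.ndarray:
    s = series.astype(str).str.strip()
    bad = ~s.isin(["0", "1"])
    if bad.any():
        first = s[bad].iloc[0]
        raise FormatError(
            f"{path}: column {column!r} must be 0/1, got {first!r}"
        )
    return (s == "1").to_numpy()


def read_unified_predictions(path) -> list[ProteinPrediction]:
    """Read the unified per-protein prediction TSV (booleans strictly 0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PREDICTION_COLUMNS, path)
    if df.empty:
        return []
    bools = {c: _parse_bool01(df[c], c, path) for c in _BOOL_COLUMNS}
    try:
        lengths = df["length_aa"].astype(int).to_numpy()
    except ValueError as e:
        raise FormatError(f"{path}: length_aa must be an integer ({e})") from None
    dup = df.duplicated(subset=["species_id", "protein_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate (species, protein) "
            f"({row['species_id']}, {row['protein_id']})"
        )
    out = []
    for i in range(len(df)):
        out.append(
            ProteinPrediction(
                protein_id=df["protein_id"].iat[i],
                species_id=df["species_id"].iat[i],
                length_aa=int(lengths[i]),
                complete_orf=bool(bools["complete_orf"][i]),
                nss_votes=(
                    bool(bools["nss_signalp"][i]),
                    bool(bools["nss_phobius"][i]),
                    bool(bools["nss_targetp"][i]),
                ),
                tm_votes=(
                    bool(bools["tm_tmhmm"][i]),
                    bool(bools["tm_memsat"][i]),
                    bool(bools["tm_phobius"][i]),
                ),
                loc_votes=(
                    bool(bools["loc_apoplastp"][i]),
                    bool(bools["loc_deeploc"][i]),
                    bool(bools["loc_msubp"][i]),
                ),
            )
        )
    return out


def write_unified_predictions(predictions: list[ProteinPrediction], path) -> None:
    rows = []
    for p in sorted(predictions, key=lambda p: (p.species_id, p.protein_id)):
        rows.append(
            [
                p.protein_id,
                p.species_id,
                p.length_aa,
                int(p.complete_orf),
                *(int(v) for v in p.nss_votes),
                *(int(v) for v in p.tm_votes),
                *(int(v) for v in p.loc_votes),
            ]
        )
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_species(path) -> list[SpeciesRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df, ["species_id", "ams_status", "lineage", "n_proteins_annotated"], path
    )
    out = []
    for _, row in df.iterrows():
        try:
            status = AmsStatus(row["ams_status"])
            lineage = Lineage(row["lineage"])
        except ValueError as e:
            raise FormatError(f"{path}: {e}") from None
        out.append(
            SpeciesRecord(
                species_id=row["species_id"],
                ams_status=status,
                lineage=lineage,
                n_proteins_annotated=int(row["n_proteins_annotated"]),
            )
        )
    if len({s.species_id for s in out}) != len(out):
        raise FormatError(f"{path}: duplicate species_id")
    return out


def write_species(species: list[SpeciesRecord], path) -> None:
    rows = [
        [s.species_id, s.ams_status.value, s.lineage.value, s.n_proteins_annotated]
        for s in sorted(species, key=lambda s: s.species_id)
    ]
    pd.DataFrame(
        rows, columns=["species_id", "ams_status", "lineage", "n_proteins_annotated"]
    ).to_csv(path, sep="\t", index=False)


def read_orthogroups(path, known_species: list[str] | None = None) -> list[OrthologGroup]:
    """Read an OrthoFinder-dialect Orthogroups.tsv.

    First column: group id.  One column per species (header = species id),
    cells holding comma-space-separated gene lists; an empty cell means no
    members in that species.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a group-id column plus species columns")
    species_cols = list(df.columns[1:])
    if known_species is not None:
        unknown = sorted(set(species_cols) - set(known_species))
        if unknown:
            raise FormatError(f"{path}: unknown species column(s) {unknown}")
    groups = []
    for _, row in df.iterrows():
        gid = row.iloc[0].strip()
        if not gid:
            raise FormatError(f"{path}: empty group id")
        members = set()
        for sp in species_cols:
            cell = row[sp].strip()
            if not cell:
                continue
            for gene in cell.split(","):
                gene = gene.strip()
                if gene:
                    members.add((sp, gene))
        groups.append(OrthologGroup(group_id=gid, members=members))
    if len({g.group_id for g in groups}) != len(groups):
        raise FormatError(f"{path}: duplicate group id")
    return groups


def write_orthogroups(
    groups: list[OrthologGroup], species_ids: list[str], path
) -> None:
    header = ["Orthogroup"] + list(species_ids)
    rows = []
    for g in sorted(groups, key=lambda g: g.group_id):
        cells = [g.group_id]
        for sp in species_ids:
            genes = sorted(gene for s, gene in g.members if s == sp)
            cells.append(", ".join(genes))
        rows.append(cells)
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


DE_COLUMNS = ["gene_id", "species_id", "contrast_id", "log2fc", "padj", "direction"]


def read_de_table(path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, DE_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        try:
            log2fc = float(row["log2fc"])
            padj = float(row["padj"])
        except ValueError as e:
            raise FormatError(f"{path}: {e}") from None
        if np.isnan(log2fc) or np.isnan(padj):
            raise FormatError(f"{path}: NaN in required numeric field")
        out.append(
            DERecord(
                gene_id=row["gene_id"],
                species_id=row["species_id"],
                contrast_id=row["contrast_id"],
                log2fc=log2fc,
                padj=padj,
                direction=Direction(row["direction"]),
            )
        )
    return out


def write_de_table(records: list[DERecord], path) -> None:
    rows = [
        [r.gene_id, r.species_id, r.contrast_id, repr(r.log2fc), repr(r.padj),
         r.direction.value]
        for r in sorted(records, key=lambda r: (r.contrast_id, r.gene_id))
    ]
    pd.DataFrame(rows, columns=DE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples numeric TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: NaN in expression/count matrix")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.sort_index().to_csv(path, sep="\t", index_label="gene_id")


CALL_COLUMNS = [
    "protein_id",
    "species_id",
    "is_ssp",
    "category",
    "nss_consensus",
    "tm_any",
    "extra_consensus",
]


def write_calls(calls: list[SSPCall], path) -> None:
    rows = [
        [
            c.protein_id,
            c.species_id,
            int(c.is_ssp),
            c.category.value,
            int(c.nss_consensus),
            int(c.tm_any),
            int(c.extra_consensus),
        ]
        for c in sorted(calls, key=lambda c: (c.species_id, c.protein_id))
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[SSPCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, CALL_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        out.append(
            SSPCall(
                protein_id=row["protein_id"],
                species_id=row["species_id"],
                is_ssp=row["is_ssp"] == "1",
                category=SSPCategory(row["category"]),
                nss_consensus=row["nss_consensus"] == "1",
                tm_any=row["tm_any"] == "1",
                extra_consensus=row["extra_consensus"] == "1",
            )
        )
    return out


def write_classifications(classifications: list[GroupClassification], path) -> None:
    rows = [
        [
            c.group_id,
            c.ssp_source.value,
            int(c.ams_specific),
            int(c.ams_preferential),
            "" if c.wilcoxon_p is None else repr(c.wilcoxon_p),
            repr(c.ams_species_fraction),
        ]
        for c in sorted(classifications, key=lambda c: c.group_id)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "ssp_source",
            "ams_specific",
            "ams_preferential",
            "wilcoxon_p",
            "ams_species_fraction",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_classifications(path) -> list[GroupClassification]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            GroupClassification(
                group_id=row["group_id"],
                ssp_source=SSPSource(row["ssp_source"]),
                ams_specific=row["ams_specific"] == "1",
                ams_preferential=row["ams_preferential"] == "1",
                wilcoxon_p=None if row["wilcoxon_p"] == "" else float(row["wilcoxon_p"]),
                ams_species_fraction=float(row["ams_species_fraction"]),
            )
        )
    return out


def write_edges(edges: list[CoexpressionEdge], path) -> None:
    rows = [
        [e.gene_a, e.gene_b, repr(e.pcc), repr(e.p_value)]
        for e in sorted(edges, key=lambda e: (e.gene_a, e.gene_b))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "p_value"]).to_csv(
        path, sep="\t", index=False
    )


def read_edges(path) -> list[CoexpressionEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        CoexpressionEdge(
            gene_a=row["gene_a"],
            gene_b=row["gene_b"],
            pcc=float(row["pcc"]),
            p_value=float(row["p_value"]),
        )
        for _, row in df.iterrows()
    ]


def write_sif(edges: list[CoexpressionEdge], path) -> None:
    """Cytoscape-compatible SIF export (interaction type ``pcc``)."""
    with open(path, "w") as fh:
        for e in sorted(edges, key=lambda e: (e.gene_a, e.gene_b)):
            fh.write(f"{e.gene_a}\tpcc\t{e.gene_b}\n")


def write_ranks(ranks: list[SSPRank], path) -> None:
    rows = [
        [r.gene_id, r.species_id, r.rank.value]
        for r in sorted(ranks, key=lambda r: (r.species_id, r.gene_id))
    ]
    pd.DataFrame(rows, columns=["gene_id", "species_id", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def read_ranks(path) -> list[SSPRank]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SSPRank(row["gene_id"], row["species_id"], Rank(row["rank"]))
        for _, row in df.iterrows()
    ]


def read_annotation(path) -> dict[str, str]:
    """gene_id -> functional category table (TSV, two required columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["gene_id", "category"], path)
    return dict(zip(df["gene_id"], df["category"]))


def genome_comparisons_to_dict(comparisons: list[GenomeComparison]) -> list[dict]:
    return [
        {
            "metric": c.metric,
            "stratum": c.stratum,
            "p_value": c.p_value,
            "direction": c.direction,
            "n_ams": c.n_ams,
            "n_non_ams": c.n_non_ams,
            "skipped_reason": c.skipped_reason,
        }
        for c in comparisons
    ]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_protein_fasta(sequences: dict[str, str], path) -> None:
    """Write protein sequences (id -> sequence) sorted by id."""
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def completeness_from_sequence(seq: str) -> bool:
    """Heuristic ORF completeness: starts with Met, no internal stop.

    Used only when no annotation flag is supplied; a trailing ``*`` (stop)
    is accepted and stripped before the internal-stop check.
    """
    seq = seq.rstrip("*")
    return seq.startswith("M") and "*" not in seq


# ---------------------------------------------------------------------------
# Best-effort raw tool-output converters (convenience only)
# ---------------------------------------------------------------------------

def parse_signalp5_short(path) -> set[str]:
    """Protein ids predicted to carry a signal peptide (SignalP 5 short format).

    Lines: ``<id>\t<Prediction>\t...`` with comment lines starting '#';
    positive when the prediction field starts with 'SP'.
    """
    positives = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: malformed SignalP line {line!r}")
        if fields[1].strip().upper().startswith("SP"):
            positives.add(fields[0].strip())
    return positives


def parse_tmhmm_short(path) -> set[str]:
    """Protein ids with >= 1 predicted TM helix (TMHMM short format).

    Lines carry whitespace-separated ``key=value`` fields including
    ``PredHel=N``.
    """
    positives = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        pred = [f for f in fields if f.startswith("PredHel=")]
        if not pred:
            raise FormatError(f"{path}: no PredHel field in line {line!r}")
        if int(pred[0].split("=", 1)[1]) > 0:
            positives.add(fields[0])
    return positives


def parse_phobius_short(path) -> tuple[set[str], set[str]]:
    """(signal-peptide positives, TM positives) from Phobius short format.

    Columns: id, TM (helix count), SP (Y or 0), prediction string.
    """
    sp_pos, tm_pos = set(), set()
    for line in Path(path).read_text().splitlines():
        # the stock header reads "SEQENCE ID" (sic)
        if not line.strip() or line.lower().startswith(("sequence", "seqence")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"{path}: malformed Phobius line {line!r}")
        pid, tm, sp = fields[0], fields[1], fields[2]
        if int(tm) > 0:
            tm_pos.add(pid)
        if sp.upper() == "Y":
            sp_pos.add(pid)
    return sp_pos, tm_pos
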