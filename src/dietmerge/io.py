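"""File interchange: TSV tables, FASTA sequences, YAML configuration.

The interchange dialect is UTF-8 TSV with a header row; lines starting
with "#" are comments. Lineage strings use a configurable separator
(default ";"). One count matrix and one FASTA per marker; detection and
merged tables are long-format TSV.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .esv import ESVTable, ExclusionPolicy, HitTable, MarkerConfig, ProvenanceLog
from .merge import Detection, MergedSample
from .taxonomy import LINNAEAN, Lineage, RankLadder, TaxonLabel, parse_lineage

PathLike = Union[str, Path]

__all__ = [
    "PipelineConfig",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_hits",
    "read_esv_table",
    "read_detections",
    "write_detections",
    "write_merged",
    "write_reduction_summary",
    "write_provenance",
    "load_config",
]


def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_fasta(path: PathLike) -> dict[str, str]:
    """ESV id → uppercase sequence."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=esv, description="")
        for esv, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_counts(path: PathLike) -> pd.DataFrame:
    """Count matrix TSV: first column = esv_id, remaining = sample ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path: PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="esv_id")


def read_esv_table(
    marker: str, fasta_path: PathLike, counts_path: PathLike
) -> ESVTable:
    return ESVTable(
        marker=marker,
        sequences=read_fasta(fasta_path),
        counts=read_counts(counts_path),
    )


def read_hits(
    path: PathLike, ladder: RankLadder = LINNAEAN, sep: str = ";"
) -> HitTable:
    """Hit table TSV with columns esv_id, lineage, pct_identity."""
    df = _read_tsv(path)
    rows = tuple(
        (r["esv_id"], parse_lineage(r["lineage"], ladder, sep),
         float(r["pct_identity"]))
        for _, r in df.iterrows()
    )
    return HitTable(rows=rows)


def read_detections(
    path: PathLike, ladder: RankLadder = LINNAEAN, sep: str = ";"
) -> list[Detection]:
    """Detections TSV: sample_id, marker_id, lineage, motu_label.

    ``motu_label`` is an integer for MOTUs, empty for species-level taxa.
    """
    df = _read_tsv(path)
    out = []
    for _, r in df.iterrows():
        lineage = parse_lineage(r["lineage"], ladder, sep)
        raw = r.get("motu_label")
        motu = None if pd.isna(raw) or raw == "" else int(float(raw))
        out.append(
            Detection(
                sample=str(r["sample_id"]),
                marker=str(r["marker_id"]),
                taxon=TaxonLabel(lineage=lineage, motu=motu),
            )
        )
    return out


def write_detections(
    detections: Sequence[Detection], path: PathLike, sep: str = ";"
) -> None:
    rows = [
        {
            "sample_id": d.sample,
            "marker_id": d.marker,
            "lineage": d.lineage.format(sep),
            "motu_label": "" if d.taxon.motu is None else d.taxon.motu,
        }
        for d in detections
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "marker_id", "lineage", "motu_label"]
    ).to_csv(path, sep="\t", index=False)


def write_merged(
    merged: Sequence[MergedSample], path: PathLike, sep: str = ";"
) -> None:
    """Merged TSV: one row per group with representative and provenance."""
    rows = []
    for m in merged:
        for g in m.groups:
            rows.append(
                {
                    "sample_id": m.sample,
                    "representative_lineage": g.representative.lineage.format(sep),
                    "motu_label": "" if g.representative.motu is None
                    else g.representative.motu,
                    "n_markers": g.n_markers,
                    "member_markers": ",".join(d.marker for d in g.members),
                    "member_lineages": ",".join(
                        d.lineage.format(sep) for d in g.members
                    ),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "representative_lineage", "motu_label",
            "n_markers", "member_markers", "member_lineages",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_reduction_summary(summary: dict, path: PathLike) -> None:
    rows = [
        {"scope": "total", "before": summary["before"],
         "after": summary["after"],
         "reduction": summary["reduction"]}
    ]
    for k, v in summary["by_kingdom"].items():
        rows.append(
            {"scope": k, "before": v["before"], "after": v["after"],
             "reduction": v["before"] - v["after"]}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_provenance(log: ProvenanceLog, path: PathLike) -> None:
    log.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """Whole-run configuration loaded from YAML."""

    ladder: RankLadder
    markers: tuple[MarkerConfig, ...]
    policy: ExclusionPolicy
    lca_tolerance: float = 1.0
    merge_exact: bool = True
    seed: int = 0
    lineage_sep: str = ";"

    def __post_init__(self) -> None:
        ids = [m.marker for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")

    def marker(self, marker_id: str) -> MarkerConfig:
        for m in self.markers:
            if m.marker == marker_id:
                return m
        raise KeyError(marker_id)


def load_config(path: PathLike) -> PipelineConfig:
    """Load a YAML pipeline configuration.

    Expected keys: ``markers`` (list of marker blocks with id, min_len,
    max_len and optional overrides), optional ``ranks``, ``exclusion``
    (allowed_kingdoms / excluded_clades), ``lca_tolerance``,
    ``merge_exact``, ``seed``, ``lineage_sep``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ladder = RankLadder(tuple(raw.get("ranks", LINNAEAN.ranks)))
    markers = tuple(
        MarkerConfig(
            marker=m["id"],
            min_len=int(m["min_len"]),
            max_len=int(m["max_len"]),
            min_pcr_reads=int(m.get("min_pcr_reads", 100)),
            rel_abundance_floor=float(m.get("rel_abundance_floor", 0.01)),
            motu_identity=float(m.get("motu_identity", 0.98)),
        )
        for m in raw["markers"]
    )
    excl = raw.get("exclusion", {})
    policy = ExclusionPolicy(
        allowed_kingdoms=tuple(
            excl.get("allowed_kingdoms", ExclusionPolicy.allowed_kingdoms)
        ),
        excluded_clades=tuple(
            excl.get("excluded_clades", ExclusionPolicy.excluded_clades)
        ),
    )
    return PipelineConfig(
        ladder=ladder,
        markers=markers,
        policy=policy,
        lca_tolerance=float(raw.get("lca_tolerance", 1.0)),
        merge_exact=bool(raw.get("merge_exact", True)),
        seed=int(raw.get("seed", 0)),
        lineage_sep=str(raw.get("lineage_sep", ";")),
    )
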