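"""End-to-end pipeline: pre-process -> cluster -> filter -> taxonomy.

One function, :func:`run_pipeline`, wires the stages together exactly the
way the module-level APIs compose, writing standard artifacts (demuxed
FASTQ, centroid FASTA, OTU table TSV, filtered table, taxonomy TSV) plus
a run report.  The pipeline is a pure function of (inputs, config, seed):
identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import cluster as _cluster
from . import mockfilter as _mockfilter
from . import preprocess as _pre
from . import seqio as _seqio
from . import taxonomy as _tax

logger = logging.getLogger("mycoamp")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run (JSON round-trippable)."""

    input_fastq: str
    outdir: str
    platform: str = "iontorrent"  # 'iontorrent' (inline barcode) or 'illumina'
    sheet: Optional[str] = None  # TSV sample sheet; required for iontorrent
    barcode_edits: int = 0
    primer_edits: int = 2
    max_len: int = 300
    min_len: int = 50
    mode: str = "fulllength"  # fulllength | pad | truncate
    max_ee: float = 1.0
    id_threshold: float = 0.97
    min_size: int = 2
    chimera_check: bool = True
    mock_sample: Optional[str] = None
    mock_fasta: Optional[str] = None
    bleed: Optional[float] = None  # user override; None => estimate from mock
    bleed_combine: str = "max"
    drop_mock: bool = True
    taxonomy_fasta: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if self.platform not in ("iontorrent", "illumina"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.platform == "iontorrent" and not self.sheet:
            raise ValueError("iontorrent input needs a sample sheet")
        if self.mode not in ("fulllength", "pad", "truncate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mock_sample and not self.mock_fasta and self.bleed is None:
            raise ValueError("mock filtering needs --mock-fasta or --bleed")
        if self.mock_fasta and not self.mock_sample:
            raise ValueError(
                "a mock reference was given but no --mock-sample names the "
                "spike-in sample column"
            )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _preprocess_labeled(reads, sheet, cfg) -> tuple[list, _pre.DemuxStats]:
    """Primer strip + length handling for pre-demultiplexed (labeled) reads."""
    stats = _pre.DemuxStats(kept={})
    rc_rev = _pre.revcomp(sheet.rev_primer)
    out = []
    for read in reads:
        if read.sample is None:
            stats.rejected["no_barcode"] += 1
            continue
        fwd_hit = _pre.find_primer(read.seq, sheet.fwd_primer, cfg.primer_edits)
        if fwd_hit is None:
            stats.rejected["no_fwd_primer"] += 1
            continue
        insert = read.seq[fwd_hit.end :]
        rev_hit = _pre.find_primer(insert, rc_rev, cfg.primer_edits)
        rev_found = rev_hit is not None
        if rev_found:
            insert = insert[: rev_hit.start]
        qual = (
            read.qual[fwd_hit.end : fwd_hit.end + len(insert)]
            if read.qual is not None
            else None
        )
        if len(insert) < cfg.min_len:
            stats.rejected["too_short"] += 1
            continue
        if len(insert) > cfg.max_len:
            insert, qual = insert[: cfg.max_len], qual[: cfg.max_len] if qual else qual
        elif cfg.mode == "truncate" and len(insert) < cfg.max_len:
            stats.rejected["too_short"] += 1
            continue
        elif cfg.mode == "pad" and len(insert) < cfg.max_len:
            pad = cfg.max_len - len(insert)
            insert += "N" * pad
            if qual is not None:
                qual = qual + [2] * pad
        elif cfg.mode == "fulllength" and not rev_found:
            stats.rejected["no_rev_primer_short"] += 1
            continue
        stats.kept[read.sample] = stats.kept.get(read.sample, 0) + 1
        out.append(
            _seqio.Read(id=read.id, seq=insert, qual=qual, sample=read.sample)
        )
    return out, stats


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all requested stages; returns a dict of artifact paths."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_lines: list[str] = []
    artifacts: dict[str, str] = {}

    if config.sheet:
        sheet = _seqio.read_sample_sheet(config.sheet)
    else:
        raise ValueError("a sample sheet (for primers and barcodes) is required")

    # (i) pre-process
    reads = _seqio.read_fastq(config.input_fastq)
    if config.platform == "iontorrent":
        demuxed, stats = _pre.demux_single(
            reads,
            sheet,
            barcode_edits=config.barcode_edits,
            primer_edits=config.primer_edits,
            max_len=config.max_len,
            mode=config.mode,
            min_len=config.min_len,
        )
    else:
        demuxed, stats = _preprocess_labeled(reads, sheet, config)
    assert stats.total == stats.n_kept + stats.n_rejected
    demux_path = outdir / "demux.fastq"
    _seqio.write_fastq(demuxed, demux_path)
    artifacts["demux"] = str(demux_path)
    report_lines.append(f"pre-process: kept {stats.n_kept}, rejected {stats.n_rejected}")
    logger.info("pre-process: kept %d rejected %d", stats.n_kept, stats.n_rejected)

    # (ii) cluster; centroids come from EE-filtered reads, counts never do
    filtered_reads = _pre.filter_by_ee(demuxed, config.max_ee)
    uniques = _cluster.dereplicate(filtered_reads)
    otus = _cluster.cluster_otus(
        uniques,
        id_threshold=config.id_threshold,
        min_size=config.min_size,
        chimera_check=config.chimera_check,
    )
    otus_path = outdir / "otus.fasta"
    _seqio.write_fasta(
        [_seqio.Read(id=o.otu_id, seq=o.centroid) for o in otus], otus_path
    )
    artifacts["otus"] = str(otus_path)
    table = _cluster.map_reads_to_otus(demuxed, otus, config.id_threshold)
    table_path = outdir / "otu_table.tsv"
    table.to_tsv(table_path)
    artifacts["otu_table"] = str(table_path)
    report_lines.append(
        f"cluster: {len(otus)} OTUs from {len(uniques)} uniques; "
        f"table {int(table.df.values.sum())} reads"
    )

    # (iii) mock-calibrated tag-switching filter
    if config.mock_sample:
        mock_map = None
        if config.mock_fasta:
            mock_refs = [(r.id, r.seq) for r in _seqio.read_fasta(config.mock_fasta)]
            mock_map = _mockfilter.map_otus_to_mock(otus, mock_refs)
        if config.bleed is not None:
            applied = config.bleed
            report_lines.append(f"filter: user-supplied bleed {applied:.6f}")
        else:
            est = _mockfilter.estimate_bleed(
                table, config.mock_sample, mock_map, combine=config.bleed_combine
            )
            applied = est.applied
            report_lines.append(
                f"filter: bleed in={est.rate_in:.6f} out={est.rate_out:.6f} "
                f"applied={applied:.6f} ({config.bleed_combine})"
            )
        filtered = _mockfilter.filter_table(
            table,
            applied,
            mock_map=mock_map,
            mock_sample=config.mock_sample,
            drop_mock=config.drop_mock,
        )
        filtered_path = outdir / "filtered.tsv"
        filtered.to_tsv(filtered_path)
        artifacts["filtered"] = str(filtered_path)

    # (iv) taxonomy
    if config.taxonomy_fasta:
        db = _tax.RefDB.from_fasta(config.taxonomy_fasta)
        tax_path = outdir / "taxonomy.tsv"
        with open(tax_path, "w") as fh:
            fh.write("otu_id\tmethod\tlineage\n")
            for otu in otus:
                ga = _tax.top_hit_global(otu.centroid, db)
                clf = _tax.classify_kmer_bootstrap(
                    otu.centroid, db, seed=config.seed
                )
                lineage = _tax.hybrid_assign(ga, clf, db)
                fh.write(f"{otu.otu_id}\t{lineage.method}\t{lineage.to_string()}\n")
        artifacts["taxonomy"] = str(tax_path)
        report_lines.append(f"taxonomy: assigned {len(otus)} OTUs")

    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(report_lines) + "\n")
    artifacts["report"] = str(report_path)
    return artifacts
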