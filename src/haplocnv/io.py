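"""Readers/writers for the standard formats and the run configuration.

All genomic intervals are 0-based half-open internally (BED convention); the
VCF writers are the only 1-based surface.  Every output file carries a header
comment naming the producing stage and the configuration hash.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .depthnorm import QCThresholds
from .rarecnv import CNVCall, HMMConfig
from .simcohort import CohortConfig, HaplotypePanel, ReadCountMatrix, SimTruth, TrioSet

__all__ = [
    "RunConfig",
    "config_hash",
    "write_panel_vcf",
    "read_panel_vcf",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_calls_bed",
    "read_calls_bed",
    "write_calls_vcf",
    "write_truth_json",
    "write_trios_fam",
    "write_pileups_tsv",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters for a pipeline run, serialized alongside outputs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    hmm: HMMConfig = field(default_factory=HMMConfig)
    k_reference: int = 20
    n_trios: int = 0
    # planted CNVs: (founder_hap, start_bin, end_bin, copy_change)
    events: tuple[tuple[int, int, int, int], ...] = ()
    stages: tuple[str, ...] = ("simulate", "normalize", "match", "call-rare")
    outdir: str = "haplocnv_run"

    @staticmethod
    def from_dict(data: dict) -> "RunConfig":
        cfg = RunConfig()
        nested = {"cohort": CohortConfig, "qc": QCThresholds, "hmm": HMMConfig}
        for key, value in data.items():
            if key in nested:
                allowed = {f.name for f in fields(nested[key])}
                unknown = set(value) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in {key!r}: {sorted(unknown)}")
                sub = getattr(cfg, key)
                for k, v in value.items():
                    if k == "ibd_thresholds":
                        v = tuple(v)
                    setattr(sub, k, v)
            elif key == "events":
                cfg.events = tuple(tuple(ev) for ev in value)
            elif key in {f.name for f in fields(RunConfig)}:
                setattr(cfg, key, tuple(value) if key == "stages" else value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _header(stage: str, chash: str) -> str:
    return f"# haplocnv stage={stage} config={chash}\n"


# ---------------------------------------------------------------------------
# haplotype panel VCF
# ---------------------------------------------------------------------------

def write_panel_vcf(panel: HaplotypePanel, path: str, stage: str = "simulate", chash: str = "-") -> None:
    """Write a phased biallelic VCF (GT like "0|1"); POS is 1-based."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=haplocnv stage={stage} config={chash}",
        f"##contig=<ID={panel.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.sample_ids),
    ]
    for j in range(panel.n_sites):
        gts = "\t".join(
            f"{panel.alleles[2 * s, j]}|{panel.alleles[2 * s + 1, j]}"
            for s in range(len(panel.sample_ids))
        )
        lines.append(
            f"{panel.chrom}\t{panel.site_pos[j] + 1}\tsite{j:05d}\tA\tG\t.\tPASS\tCM={panel.site_cm[j]:.6f}\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_panel_vcf(path: str, cm_per_bp: float | None = None) -> tuple[HaplotypePanel, dict[str, int]]:
    """Read a phased biallelic VCF into a haplotype panel.

    Unphased or multiallelic records are rejected and counted; the rejection
    counts are returned alongside the panel.  Genetic-map coordinates are read
    from a CM INFO key when present, otherwise derived linearly from bp.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF has no samples")
    cols: list[np.ndarray] = []
    pos: list[int] = []
    cms: list[float] = []
    rejected = {"unphased": 0, "multiallelic": 0, "missing_gt": 0}
    chrom = None
    for rec in vcf:
        if len(rec.ALT) != 1:
            rejected["multiallelic"] += 1
            continue
        gts = rec.genotypes  # [a, b, phased] per sample
        if any(len(g) != 3 for g in gts):
            raise ValueError("mixed ploidy in VCF")
        if any(g[0] < 0 or g[1] < 0 for g in gts):
            rejected["missing_gt"] += 1
            continue
        if not all(g[2] for g in gts):
            rejected["unphased"] += 1
            continue
        chrom = rec.CHROM
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, g in enumerate(gts):
            col[2 * i], col[2 * i + 1] = g[0], g[1]
        cols.append(col)
        pos.append(rec.POS - 1)
        cm = rec.INFO.get("CM")
        cms.append(float(cm) if cm is not None else np.nan)
    if not cols:
        raise ValueError("no usable phased biallelic records in VCF")
    alleles = np.stack(cols, axis=1)
    site_pos = np.asarray(pos, dtype=np.int64)
    site_cm = np.asarray(cms)
    if np.any(np.isnan(site_cm)):
        site_cm = site_pos * (cm_per_bp if cm_per_bp is not None else 1e-4)
    panel = HaplotypePanel(alleles, site_pos, site_cm, samples, chrom=chrom or "chr1")
    return panel, rejected


# ---------------------------------------------------------------------------
# read-count matrices, truth, trios, pileups
# ---------------------------------------------------------------------------

def write_counts_tsv(matrix: ReadCountMatrix, path: str, stage: str = "simulate", chash: str = "-") -> None:
    """Counts as (gzipped if *.gz) TSV: rows samples, cols bins, plus a lot column.

    Gzip output is written with a zeroed mtime so reruns are bit-identical.
    """
    df = pd.DataFrame(matrix.counts, index=matrix.sample_ids, columns=matrix.bin_ids)
    df.insert(0, "lot", matrix.lots)
    body = _header(stage, chash) + df.to_csv(sep="\t", index_label="sample")
    if str(path).endswith(".gz"):
        with open(path, "wb") as raw, gzip.GzipFile(
            filename="", fileobj=raw, mode="wb", mtime=0
        ) as gz:
            gz.write(body.encode())
    else:
        with open(path, "w") as fh:
            fh.write(body)


def read_counts_tsv(path: str) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample")
    lots = df.pop("lot").to_numpy()
    return ReadCountMatrix(
        counts=df.to_numpy(dtype=np.int64),
        sample_ids=list(df.index),
        bin_ids=list(df.columns),
        lots=lots,
    )


def write_truth_json(truth: SimTruth, path: str, stage: str = "simulate", chash: str = "-") -> None:
    payload = {
        "_meta": {"stage": stage, "config": chash},
        "events": [
            {
                "founder_hap": ev.founder_hap,
                "start_bin": ev.start_bin,
                "end_bin": ev.end_bin,
                "copy_change": ev.copy_change,
                "carrier_haps": truth.carrier_haps[i].tolist(),
            }
            for i, ev in enumerate(truth.events)
        ],
        "trio_index": truth.trio_index,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_trios_fam(trios: TrioSet, path: str, stage: str = "simulate", chash: str = "-") -> None:
    """FAM-style TSV: family, individual, father, mother, sex, phenotype."""
    with open(path, "w") as fh:
        fh.write(_header(stage, chash))
        for i, (f, m, c) in enumerate(trios.trio_index):
            fh.write(f"FAM{i:05d}\t{f}\t0\t0\t1\t-9\n")
            fh.write(f"FAM{i:05d}\t{m}\t0\t0\t2\t-9\n")
            fh.write(f"FAM{i:05d}\t{c}\t{f}\t{m}\t0\t-9\n")


def write_pileups_tsv(pileups: pd.DataFrame, path: str, stage: str = "psv", chash: str = "-") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, chash))
        pileups.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNV calls: BED9 and symbolic-allele VCF
# ---------------------------------------------------------------------------

_BED_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "type", "sample", "thresholds",
]


def write_calls_bed(calls: list[CNVCall], path: str, stage: str = "call-rare", chash: str = "-") -> None:
    """BED9 plus type/sample/threshold-provenance columns; 0-based half-open."""
    with open(path, "w") as fh:
        fh.write(_header(stage, chash))
        for c in calls:
            rgb = "255,0,0" if c.type == "DEL" else "0,0,255"
            thr = ",".join(f"{t:g}" for t in c.thresholds) or "."
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample}:{c.type}\t{c.score:.6g}\t.\t"
                f"{c.start}\t{c.end}\t{rgb}\t{c.type}\t{c.sample}\t{thr}\n"
            )


def read_calls_bed(path: str) -> list[CNVCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            thresholds = [] if f[11] == "." else [float(t) for t in f[11].split(",")]
            calls.append(
                CNVCall(
                    sample=f[10],
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    type=f[9],
                    score=float(f[4]),
                    ibd_threshold=None,
                    n_bins=max((int(f[2]) - int(f[1])) // 100, 1),
                    thresholds=thresholds,
                )
            )
    return calls


def write_calls_vcf(
    calls: list[CNVCall], path: str, contig_lengths: dict[str, int] | None = None,
    stage: str = "call-rare", chash: str = "-",
) -> None:
    """Symbolic-allele VCF (<DEL>/<DUP>) with END info; POS is 1-based."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=haplocnv stage={stage} config={chash}",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample">',
    ]
    for chrom in sorted({c.chrom for c in calls}):
        length = (contig_lengths or {}).get(chrom)
        lines.append(f"##contig=<ID={chrom}" + (f",length={length}>" if length else ">"))
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, c in enumerate(calls):
        if contig_lengths and c.end > contig_lengths.get(c.chrom, np.inf):
            raise ValueError(f"call interval outside contig bounds: {c.chrom}:{c.start}-{c.end}")
        lines.append(
            f"{c.chrom}\t{c.start + 1}\tcnv{i:06d}\tN\t<{c.type}>\t{c.score:.4g}\tPASS\t"
            f"END={c.end};SVTYPE={c.type};SAMPLE={c.sample}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
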