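"""Readers/writers for the pipeline's interchange formats and orchestration.

Formats: binned coverage as TSV (chrom, start, end, gc, count, blacklisted);
variants as a minimal text VCF (INFO keys GENE/AF/AD/DP/POPFREQ_*/EFFECT/
SIFT/COSMIC/HOTSPOT/RECUR, unknown keys preserved) or an equivalent TSV
dialect; CNV segments as BED (0-based) plus a human-readable TSV with
1-based printed coordinates; the sample manifest as TSV; cohort statistics
as JSON.  ``run_pipeline`` chains CNV calling, SNV filtering, lineage
classification, CNV-SNV integration and the statistical battery over a
manifest, embedding a provenance block (config hash, seed, version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__ as _VERSION
from .cnv import (BinnedCoverage, CnvSegment, annotate_recurrence,
                  compute_scores, default_catalog, gc_correct,
                  karyotype_status, segment)
from .core import PipelineConfig, SampleMeta, check_manifest_order
from .integrate import association_table, match_af
from .lineage import (ClassifiedVariant, acquisition_points, classify_variants,
                      de_novo_load, _segment_copy_number)
from .snv import VariantCall, apply_filters
from .stats import fisher_exact_2x2, logistic_acquisition_regression, \
    poisson_load_regression

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "read_coverage",
    "write_coverage",
    "read_variants",
    "write_variants_vcf",
    "write_variants_tsv",
    "write_segments",
    "read_manifest",
    "write_manifest",
    "run_pipeline",
]


# -- coverage ------------------------------------------------------------

def write_coverage(cov: BinnedCoverage, path: str | os.PathLike) -> None:
    out = cov.bins.copy()
    out["blacklisted"] = out["blacklisted"].astype(int)
    out.insert(0, "sample_id", cov.sample_id)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_coverage(path: str | os.PathLike,
                  sample_id: str | None = None) -> BinnedCoverage:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gc", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if sample_id is None:
        sample_id = (str(df["sample_id"].iloc[0]) if "sample_id" in df.columns
                     else Path(path).stem)
    if "blacklisted" not in df.columns:
        df["blacklisted"] = 0
    df["blacklisted"] = df["blacklisted"].astype(bool)
    cols = ["chrom", "start", "end", "gc", "count", "blacklisted"]
    return BinnedCoverage(sample_id, df[cols])


# -- variants ------------------------------------------------------------

_POP_KEYS = {"gnomad": "POPFREQ_GNOMAD", "1000g": "POPFREQ_1000G",
             "esp6500": "POPFREQ_ESP6500"}
_KNOWN_INFO = {"GENE", "AF", "AD", "DP", "EFFECT", "SIFT", "COSMIC",
               "HOTSPOT", "RECUR"} | set(_POP_KEYS.values())

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=stemdrift
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt read count">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth at site">
##INFO=<ID=POPFREQ_GNOMAD,Number=1,Type=Float,Description="gnomAD frequency">
##INFO=<ID=POPFREQ_1000G,Number=1,Type=Float,Description="1000 genomes frequency">
##INFO=<ID=POPFREQ_ESP6500,Number=1,Type=Float,Description="ESP6500 frequency">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Functional effect class">
##INFO=<ID=SIFT,Number=1,Type=String,Description="deleterious|tolerated|.">
##INFO=<ID=COSMIC,Number=1,Type=String,Description="none|reported|tier1">
##INFO=<ID=HOTSPOT,Number=0,Type=Flag,Description="Clinical hotspot position">
##INFO=<ID=RECUR,Number=1,Type=Float,Description="Facility recurrence frequency">
"""


def write_variants_vcf(variants: Sequence[VariantCall],
                       path: str | os.PathLike) -> None:
    """Write calls as a minimal text VCF (positions stay 1-based)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if variants:
            fh.write(f"##sample={variants[0].sample_id}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = [
                f"GENE={v.gene}",
                f"AF={v.af:.6f}",
                f"AD={v.alt_reads}",
                f"DP={v.depth}",
            ]
            for src, key in _POP_KEYS.items():
                info.append(f"{key}={v.pop_freq.get(src, 0.0):.6g}")
            info.append(f"EFFECT={v.effect}")
            sift = ("." if v.deleterious is None
                    else "deleterious" if v.deleterious else "tolerated")
            info.append(f"SIFT={sift}")
            info.append(f"COSMIC={v.cosmic}")
            if v.hotspot:
                info.append("HOTSPOT")
            info.append(f"RECUR={v.recurrence_freq:.6g}")
            for k, val in sorted(v.info.items()):
                info.append(f"{k.upper()}={val}")
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     + ";".join(info) + "\n")


def _parse_info(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.split(";"):
        if not item or item == ".":
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = "1"
    return out


def _variant_from_fields(sample_id: str, chrom: str, pos: int, ref: str,
                         alt: str, info: dict[str, str],
                         where: str) -> VariantCall:
    for key in ("GENE", "AF", "AD", "DP"):
        if key not in info:
            raise ValueError(f"{where}: missing required field {key}")
    sift = info.get("SIFT", ".")
    passthrough = {k.lower(): v for k, v in info.items()
                   if k not in _KNOWN_INFO}
    return VariantCall(
        sample_id=sample_id,
        gene=info["GENE"], chrom=chrom, pos=pos, ref=ref, alt=alt,
        af=float(info["AF"]), alt_reads=int(info["AD"]), depth=int(info["DP"]),
        pop_freq={src: float(info.get(key, 0.0))
                  for src, key in _POP_KEYS.items()},
        effect=info.get("EFFECT", "missense"),
        deleterious=None if sift == "." else sift == "deleterious",
        cosmic=info.get("COSMIC", "none"),
        hotspot=info.get("HOTSPOT", "0") == "1",
        recurrence_freq=float(info.get("RECUR", 0.0)),
        info=passthrough,
    )


def read_variants(path: str | os.PathLike, dialect: str = "vcf",
                  sample_id: str | None = None) -> list[VariantCall]:
    """Read variant calls from a VCF or the TSV dialect."""
    if dialect == "tsv":
        return _read_variants_tsv(path, sample_id)
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: list[VariantCall] = []
    sid = sample_id
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sample="):
                sid = sid or line.split("=", 1)[1]
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{ln}: truncated VCF record")
            chrom, pos_s, _, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed coordinate {pos_s!r}")
            calls.append(_variant_from_fields(
                sid or Path(path).stem, chrom, pos, ref, alt,
                _parse_info(fields[7]), f"{path}:{ln}"))
    return calls


_TSV_COLUMNS = ["sample_id", "gene", "chrom", "pos", "ref", "alt", "af",
                "alt_reads", "depth", "pop_gnomad", "pop_1000g", "pop_esp6500",
                "effect", "sift", "cosmic", "hotspot", "recurrence_freq",
                "info"]


def write_variants_tsv(variants: Sequence[VariantCall],
                       path: str | os.PathLike) -> None:
    rows = []
    for v in variants:
        rows.append({
            "sample_id": v.sample_id, "gene": v.gene, "chrom": v.chrom,
            "pos": v.pos, "ref": v.ref, "alt": v.alt, "af": f"{v.af:.6f}",
            "alt_reads": v.alt_reads, "depth": v.depth,
            "pop_gnomad": v.pop_freq.get("gnomad", 0.0),
            "pop_1000g": v.pop_freq.get("1000g", 0.0),
            "pop_esp6500": v.pop_freq.get("esp6500", 0.0),
            "effect": v.effect,
            "sift": ("." if v.deleterious is None
                     else "deleterious" if v.deleterious else "tolerated"),
            "cosmic": v.cosmic, "hotspot": int(v.hotspot),
            "recurrence_freq": v.recurrence_freq,
            "info": ";".join(f"{k}={val}" for k, val in sorted(v.info.items())),
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_variants_tsv(path: str | os.PathLike,
                       sample_id: str | None) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(_TSV_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for i, row in df.iterrows():
        info = {"GENE": row["gene"], "AF": str(row["af"]),
                "AD": str(row["alt_reads"]), "DP": str(row["depth"]),
                "POPFREQ_GNOMAD": str(row["pop_gnomad"]),
                "POPFREQ_1000G": str(row["pop_1000g"]),
                "POPFREQ_ESP6500": str(row["pop_esp6500"]),
                "EFFECT": row["effect"], "SIFT": row["sift"],
                "COSMIC": row["cosmic"], "HOTSPOT": str(int(row["hotspot"])),
                "RECUR": str(row["recurrence_freq"])}
        extra = str(row.get("info", "") or "")
        for item in extra.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                info[k.upper()] = v
        calls.append(_variant_from_fields(
            sample_id or str(row["sample_id"]), str(row["chrom"]),
            int(row["pos"]), str(row["ref"]), str(row["alt"]), info,
            f"{path}:{i + 2}"))
    return calls


# -- segments ------------------------------------------------------------

def write_segments(segments: Sequence[CnvSegment], bed_path: str | os.PathLike,
                   tsv_path: str | os.PathLike | None = None,
                   sample_id: str = "sample") -> None:
    """BED (0-based half-open) plus a printed TSV with 1-based coordinates."""
    with open(bed_path, "w") as fh:
        for s in segments:
            name = s.recurrent_label or "rare"
            fh.write(f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                     f"\t{s.direction}:{name}\n")
    if tsv_path is not None:
        rows = [{
            "sample_id": sample_id,
            "chrom": s.interval.chrom,
            "start_1based": s.interval.start + 1,
            "end": s.interval.end,
            "direction": s.direction,
            "mean_log2ratio": round(s.mean_log2ratio, 4),
            "n_bins": s.n_bins,
            "size_mb": s.size_mb,
            "recurrent_label": s.recurrent_label or "",
        } for s in segments]
        cols = ["sample_id", "chrom", "start_1based", "end", "direction",
                "mean_log2ratio", "n_bins", "size_mb", "recurrent_label"]
        pd.DataFrame(rows, columns=cols).to_csv(tsv_path, sep="\t", index=False)


# -- manifest ------------------------------------------------------------

@dataclass
class RunManifest:
    """Sample sheet: one row per sequenced sample with its input files."""

    samples: list[SampleMeta]
    coverage_paths: dict[str, str] = field(default_factory=dict)
    variant_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in manifest")
        check_manifest_order(self.samples)

    def check_files(self) -> None:
        for sid, p in list(self.coverage_paths.items()) + \
                list(self.variant_paths.items()):
            if not os.path.exists(p):
                raise FileNotFoundError(f"{sid}: missing input file {p}")


def write_manifest(manifest: RunManifest, path: str | os.PathLike) -> None:
    rows = [{
        "line_id": s.line_id, "passage": s.passage, "rank": s.rank,
        "coverage_path": manifest.coverage_paths.get(s.sample_id, ""),
        "variants_path": manifest.variant_paths.get(s.sample_id, ""),
    } for s in manifest.samples]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | os.PathLike) -> RunManifest:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    samples, cov, var = [], {}, {}
    for _, row in df.iterrows():
        s = SampleMeta(str(row["line_id"]), int(row["passage"]), int(row["rank"]))
        samples.append(s)
        if row.get("coverage_path"):
            cov[s.sample_id] = str(row["coverage_path"])
        if row.get("variants_path"):
            var[s.sample_id] = str(row["variants_path"])
    return RunManifest(samples, cov, var)


# -- orchestration -------------------------------------------------------

def _provenance(config: PipelineConfig, seed: int | None) -> dict:
    cfg_yaml = config.to_yaml()
    return {
        "tool": "stemdrift",
        "version": _VERSION,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": seed,
    }


def run_pipeline(
    manifest: RunManifest,
    config: PipelineConfig | None = None,
    out_dir: str | os.PathLike = "stemdrift_out",
    seed: int | None = None,
    variant_dialect: str = "vcf",
) -> dict:
    """Execute call-cnv -> filter-snv -> classify -> integrate -> stats.

    Writes per-sample segment files, filtered variant TSVs, a per-line
    classification table, the integration table, and a cohort ``stats.json``;
    returns the summary dict.  Any stage failure is re-raised with the stage
    and sample named.
    """
    if config is None:
        config = PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.check_files()
    catalog = default_catalog()

    segments_by_sample: dict[str, list[CnvSegment]] = {}
    retained_by_sample: dict[str, list[VariantCall]] = {}
    for s in manifest.samples:
        sid = s.sample_id
        try:
            if sid in manifest.coverage_paths:
                cov = read_coverage(manifest.coverage_paths[sid], sample_id=sid)
                scores = compute_scores(gc_correct(cov))
                segs = annotate_recurrence(segment(scores), catalog)
                segments_by_sample[sid] = segs
                write_segments(segs, out / f"{sid}.segments.bed",
                               out / f"{sid}.segments.tsv", sample_id=sid)
            else:
                segments_by_sample[sid] = []
        except Exception as exc:
            raise RuntimeError(f"stage call-cnv failed for {sid}: {exc}") from exc
        try:
            calls = read_variants(manifest.variant_paths[sid],
                                  dialect=variant_dialect, sample_id=sid) \
                if sid in manifest.variant_paths else []
            retained, report = apply_filters(calls, config)
            retained_by_sample[sid] = retained
            report.to_frame().to_csv(out / f"{sid}.filter_report.tsv",
                                     sep="\t", index=False)
            write_variants_tsv(retained, out / f"{sid}.filtered.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage filter-snv failed for {sid}: {exc}") from exc

    # classify per line
    lines: dict[str, list[SampleMeta]] = {}
    for s in manifest.samples:
        lines.setdefault(s.line_id, []).append(s)
    classified_by_line: dict[str, list[ClassifiedVariant]] = {}
    class_rows = []
    for line_id, members in lines.items():
        members = sorted(members, key=lambda s: s.rank)
        calls_by_rank = {s.rank: retained_by_sample[s.sample_id]
                         for s in members}
        segs_by_rank = {s.rank: segments_by_sample[s.sample_id]
                        for s in members}
        try:
            classified = classify_variants(line_id, calls_by_rank, segs_by_rank)
        except Exception as exc:
            raise RuntimeError(
                f"stage classify failed for line {line_id}: {exc}") from exc
        classified_by_line[line_id] = classified
        for v in classified:
            for rank, af in v.af_by_rank.items():
                class_rows.append({
                    "line_id": line_id, "gene": v.gene, "chrom": v.chrom,
                    "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "origin": v.origin, "rank": rank, "af": round(af, 6),
                    "trajectory": v.trajectory, "zygosity": v.zygosity,
                    "segment_label": v.segment_label or "",
                })
    pd.DataFrame(class_rows, columns=[
        "line_id", "gene", "chrom", "pos", "ref", "alt", "origin", "rank",
        "af", "trajectory", "zygosity", "segment_label",
    ]).to_csv(out / "classified_variants.tsv", sep="\t", index=False)

    # integrate: per-sample karyotype status x de novo carriage
    sample_labels = []
    integration_rows = []
    for s in manifest.samples:
        sid = s.sample_id
        segs = segments_by_sample[sid]
        status = karyotype_status(segs)
        classified = classified_by_line[s.line_id]
        carriage = de_novo_load(classified, s.rank) > 0
        sample_labels.append({"sample_id": sid, "karyotype": status,
                              "has_de_novo": carriage})
        for v in classified:
            if s.rank not in v.af_by_rank:
                continue
            cn, label = _segment_copy_number(v.chrom, v.pos, segs)
            rec = match_af(v.af_by_rank[s.rank], cn, segment_label=label,
                           m0_values=(0,) if v.origin == "de_novo" else (0, 1))
            integration_rows.append({
                "sample_id": sid, "gene": v.gene, "chrom": v.chrom,
                "pos": v.pos, "origin": v.origin,
                "observed_af": round(rec.observed_af, 6),
                "copy_number": rec.copy_number,
                "segment_label": rec.segment_label or "",
                "expected_af": round(rec.expected_af, 6),
                "best_m": rec.best_m, "best_m0": rec.best_m0,
                "best_f": rec.best_f, "cnv_explained": rec.cnv_explained,
            })
    pd.DataFrame(integration_rows).to_csv(out / "integration.tsv", sep="\t",
                                          index=False)

    # stats battery
    table = association_table(
        [(d["karyotype"], d["has_de_novo"]) for d in sample_labels])
    stats: dict = {
        "association_table": [[table.a, table.b], [table.c, table.d]],
        "fisher_karyotype_vs_de_novo_p": fisher_exact_2x2(table),
    }
    load_rank, load_passage, acq_passage = [], [], []
    for line_id, members in lines.items():
        classified = classified_by_line[line_id]
        rank_to_passage = {s.rank: s.passage
                           for s in sorted(members, key=lambda m: m.rank)}
        for s in members:
            load = de_novo_load(classified, s.rank)
            load_rank.append((s.rank, load))
            load_passage.append((s.passage, load))
        for _, passage, acquired in acquisition_points(classified,
                                                       rank_to_passage):
            acq_passage.append((passage, acquired))

    def _try(fit, points, **kw):
        try:
            r = fit(points, **kw)
            return {"slope": r.slope, "se": r.se, "p": r.p, "n": r.n}
        except ValueError as exc:
            return {"degenerate": str(exc)}

    stats["poisson_load_vs_rank"] = _try(poisson_load_regression, load_rank,
                                         predictor="rank")
    stats["poisson_load_vs_passage"] = _try(poisson_load_regression,
                                            load_passage, predictor="passage")
    stats["logistic_acquisition_vs_passage"] = _try(
        logistic_acquisition_regression, acq_passage, predictor="passage")
    stats["provenance"] = _provenance(config, seed)

    summary = {
        "n_samples": len(manifest.samples),
        "n_lines": len(lines),
        "samples": sample_labels,
        "stats": stats,
    }
    with open(out / "stats.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
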