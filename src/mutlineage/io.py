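"""Readers and writers for the file formats the pipeline touches.

Canonical tabular dialect: tab-separated UTF-8 with a header row; output
tables carry ``#``-prefixed comment lines recording the seed and a config
hash so any run can be reproduced.  Variant tables are a minimal VCF subset
(CHROM, POS, REF, ALT; single sample; SNVs only) or an equivalent TSV;
positions are 1-based on disk and 0-based in memory.  Callable regions are
BED (0-based, half-open).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .genome import ChromosomeSet
from .intervals import IntervalMap
from .lineage import ColonyRecord, LineageTable, Role, SegregantCounts

__all__ = [
    "read_variants", "write_variants_tsv", "read_bed", "write_bed",
    "read_counts", "write_counts", "load_lineage_manifest",
    "write_lineage_files", "write_segregant_counts", "write_run_manifest",
]


def _config_hash(config: dict) -> str:
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={_config_hash(config)}\n")
            for key in sorted(config):
                fh.write(f"# {key}={config[key]}\n")
        df.to_csv(fh, sep="\t", index=False)


# -- variants ---------------------------------------------------------------

def read_variants(path: str | Path) -> set:
    """Read a variant table: ``.vcf`` or TSV with chrom/pos/ref/alt.

    Only single-nucleotide variants are kept; positions are converted to
    0-based.  VCF reading uses pysam when available.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: variant TSV needs columns {sorted(required)}")
    out = set()
    for row in df.itertuples(index=False):
        if len(row.ref) == 1 and len(row.alt) == 1:
            out.add((row.chrom, int(row.pos) - 1, row.ref, row.alt))
    return out


def _read_vcf(path: Path) -> set:
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires pysam; "
                          "install mutlineage[vcf] or supply a TSV") from exc
    out = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1:
                    out.add((rec.chrom, rec.pos - 1, rec.ref, alt))
    return out


def write_variants_tsv(variants, path) -> None:
    rows = sorted((c, p + 1, r, a) for c, p, r, a in variants)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    df.to_csv(path, sep="\t", index=False)


# -- BED --------------------------------------------------------------------

def read_bed(path) -> IntervalMap:
    out: IntervalMap = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            out.setdefault(chrom, []).append((int(start), int(end)))
    return out


def write_bed(ivmap: IntervalMap, path) -> None:
    with open(path, "w") as fh:
        for chrom in ivmap:
            for start, end in ivmap[chrom]:
                if end > start:
                    fh.write(f"{chrom}\t{start}\t{end}\n")


# -- counts -----------------------------------------------------------------

def read_counts(path) -> list[int]:
    """One-column TSV (optionally headed ``count``) of mutation counts."""
    values = []
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if not token or token.startswith("#"):
                continue
            try:
                values.append(int(token))
            except ValueError:
                continue  # header line
    if not values:
        raise ValueError(f"{path}: no counts found")
    return values


def write_counts(counts, path, config: dict | None = None) -> None:
    _write_table(pd.DataFrame({"count": list(counts)}), path, config)


# -- lineage manifest -------------------------------------------------------

def load_lineage_manifest(path, chromset: ChromosomeSet) -> LineageTable:
    """Build a :class:`LineageTable` from a manifest TSV.

    Columns: ``colony_id``, ``division``, ``position`` (D/GD1/GD2/GGD),
    ``variants`` and ``callable`` (paths, relative to the manifest).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"colony_id", "division", "position", "variants", "callable"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(ColonyRecord(
            colony_id=row.colony_id,
            role=Role(int(row.division), row.position),
            variants=read_variants(path.parent / row.variants),
            callable=read_bed(path.parent / row.callable),
        ))
    return LineageTable(records, chromset)


def write_lineage_files(lineage: LineageTable, outdir, truth=None) -> Path:
    """Emit per-colony variant TSVs and BEDs plus a lineage manifest.

    When ``truth`` is given, the generator's ground-truth labels are
    written alongside (``ground_truth.tsv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in lineage.colonies():
        safe = rec.colony_id.replace(".", "_")
        vpath, bpath = f"{safe}.variants.tsv", f"{safe}.callable.bed"
        write_variants_tsv(rec.variants, outdir / vpath)
        write_bed(rec.callable, outdir / bpath)
        rows.append({
            "colony_id": rec.colony_id, "division": rec.role.division,
            "position": rec.role.position, "variants": vpath,
            "callable": bpath,
        })
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    lineage.chromset.to_tsv(outdir / "chromosomes.tsv")
    if truth is not None:
        truth.truth_frame().to_csv(outdir / "ground_truth.tsv",
                                   sep="\t", index=False)
    return outdir / "manifest.tsv"


# -- segregant counts -------------------------------------------------------

def write_segregant_counts(counts: list[SegregantCounts], path,
                           per_chromosome_path=None,
                           config: dict | None = None) -> None:
    rows = [{
        "division": sc.division, "Da": sc.da, "Db": sc.db,
        "Ma": sc.ma, "Mb": sc.mb, "Dm": sc.dm, "Mm": sc.mm,
        "full": sc.full, "unassigned": len(sc.unassigned),
        "censored": not sc.scorable,
    } for sc in counts]
    _write_table(pd.DataFrame(rows), path, config)
    if per_chromosome_path is not None:
        long_rows = []
        for sc in counts:
            if sc.per_chromosome is None:
                continue
            for chrom, row in sc.per_chromosome.iterrows():
                for group in ("Da", "Db", "Ma", "Mb"):
                    long_rows.append({
                        "division": sc.division, "chrom": chrom,
                        "group": group, "count": int(row[group]),
                    })
        _write_table(pd.DataFrame(
            long_rows, columns=["division", "chrom", "group", "count"]),
            per_chromosome_path, config)


def write_run_manifest(outdir, config: dict) -> None:
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"package": "mutlineage", "version": __version__,
               "config": config, "config_hash": _config_hash(config)}
    (outdir / "run_manifest.json").write_text(json.dumps(payload, indent=2,
                                                         default=str) + "\n")
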