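"""Readers/writers for the formats the pipeline touches.

FASTA, a minimal phased-GT VCF subset, BED3/4, a MEME-like PWM dialect,
and TSV tables. Internal coordinates are 0-based half-open; VCF 1-based
positions are converted here at the boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from .types import GenomicWindow, PWMMotif, VariantRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_pwm",
    "write_pwm",
    "pwm_from_tsv",
    "read_bed",
    "write_bed",
    "read_tsv",
    "write_tsv",
    "load_config",
]

logger = logging.getLogger(__name__)

_IUPAC = set("ACGTNRYSWKMBDHVU")


class FastaParseError(ValueError):
    pass


def _validate_fasta_lines(path) -> None:
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                seen_header = True
            else:
                if not seen_header:
                    raise FastaParseError(
                        f"{path}: sequence before any header at line {lineno}")
                bad = set(line.upper()) - _IUPAC
                if bad:
                    raise FastaParseError(
                        f"{path}: non-IUPAC character(s) {sorted(bad)} at line {lineno}")


def read_fasta(path) -> Dict[str, str]:
    """FASTA records as an ordered id -> uppercased sequence mapping."""
    _validate_fasta_lines(path)
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def windows_to_fasta(windows: Sequence[GenomicWindow], path) -> None:
    """Windows as FASTA with anchor/strand carried in the description."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.chrom} start={w.start} anchor={w.anchor} strand={w.strand}\n")
            for i in range(0, w.length, 60):
                fh.write(w.sequence[i:i + 60] + "\n")


def fasta_to_windows(path) -> List[GenomicWindow]:
    _validate_fasta_lines(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            part.split("=", 1) for part in rec.description.split()[1:] if "=" in part
        )
        seq = str(rec.seq).upper()
        out.append(GenomicWindow(
            chrom=rec.id,
            start=int(fields.get("start", 0)),
            sequence=seq,
            anchor=int(fields.get("anchor", len(seq) // 2)),
            strand=fields.get("strand", "+"),
        ))
    return out


# ---------------------------------------------------------------------------
# VCF (minimal subset: SNVs with phased GT)
# ---------------------------------------------------------------------------

def write_phased_vcf(
    variants: Sequence[VariantRecord],
    genotypes: Optional[np.ndarray],
    sample_ids: Sequence[str],
    path,
) -> None:
    """Minimal VCF with phased GT calls and GENE/TSSD/SIGN INFO keys.

    ``genotypes`` is (n_samples, n_variants, 2) of 0/1 alleles (may be
    None for a site-only VCF); positions are written 1-based.
    """
    chroms = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Target gene">\n')
        fh.write('##INFO=<ID=TSSD,Number=1,Type=Integer,Description="Distance to TSS">\n')
        fh.write('##INFO=<ID=SIGN,Number=1,Type=Integer,Description="True effect sign">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_ids:
            cols += ["FORMAT"] + list(sample_ids)
        fh.write("\t".join(cols) + "\n")
        for j, v in enumerate(variants):
            info = [f"GENE={v.gene_id or '.'}", f"TSSD={v.tss_distance}"]
            if v.true_sign is not None:
                info.append(f"SIGN={v.true_sign}")
            row = [v.chrom, str(v.pos + 1), v.variant_id, v.ref_allele,
                   v.alt_allele, ".", "PASS", ";".join(info)]
            if sample_ids:
                row.append("GT")
                row += [f"{genotypes[i, j, 0]}|{genotypes[i, j, 1]}"
                        for i in range(len(sample_ids))]
            fh.write("\t".join(row) + "\n")


def read_phased_vcf(path) -> Tuple[List[VariantRecord], np.ndarray]:
    """Variants and the (individuals x variants x 2) phased haplotype matrix.

    Non-SNV records are skipped (with a logged count); an unphased GT is
    an error, since haplotype construction requires phasing.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    known_info = set(vf.header.info.keys())

    def _info(rec, key, default=None):
        if key not in known_info:
            return default
        return rec.info.get(key, default)
    variants: List[VariantRecord] = []
    gt_rows: List[List[Tuple[int, int]]] = []
    skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                or rec.ref not in "ACGT" or alts[0] not in "ACGT":
            skipped += 1
            continue
        sign = _info(rec, "SIGN")
        variants.append(VariantRecord(
            chrom=rec.chrom,
            pos=rec.pos - 1,  # VCF is 1-based
            ref_allele=rec.ref,
            alt_allele=alts[0],
            gene_id=str(_info(rec, "GENE", "") or ""),
            tss_distance=int(_info(rec, "TSSD", 0) or 0),
            true_sign=None if sign is None else int(sign),
        ))
        row = []
        for s in samples:
            call = rec.samples[s]
            if len(samples) and not call.phased:
                raise ValueError(
                    f"unphased genotype for sample {s} at {rec.chrom}:{rec.pos}; "
                    "phasing is required to build haplotypes")
            alleles = call["GT"]
            if len(alleles) != 2 or any(a is None for a in alleles):
                raise ValueError(f"missing/haploid GT at {rec.chrom}:{rec.pos}")
            row.append((int(alleles[0]), int(alleles[1])))
        gt_rows.append(row)
    if skipped:
        logger.info("skipped %d non-SNV record(s) in %s", skipped, path)
    n_var = len(variants)
    n_ind = len(samples)
    matrix = np.zeros((n_ind, n_var, 2), dtype=np.int8)
    for j, row in enumerate(gt_rows):
        for i, (a, b) in enumerate(row):
            matrix[i, j, 0] = a
            matrix[i, j, 1] = b
    return variants, matrix


# ---------------------------------------------------------------------------
# PWM files (MEME-like probability-matrix blocks)
# ---------------------------------------------------------------------------

def read_pwm(path) -> List[PWMMotif]:
    """Parse MOTIF blocks of per-position A/C/G/T probability rows.

    Rows are renormalized to sum exactly 1 (tolerance 1e-6 handled by the
    motif type); a row summing outside [0.9, 1.1] is rejected as a likely
    counts matrix.
    """
    motifs: List[PWMMotif] = []
    name: Optional[str] = None
    rows: List[List[float]] = []

    def _flush():
        nonlocal name, rows
        if name is not None:
            if not rows:
                raise ValueError(f"{path}: motif {name} has no matrix rows")
            motifs.append(PWMMotif(motif_id=name, matrix=np.array(rows)))
        name, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "letter-probability")) \
                    or line.upper().startswith(("MEME VERSION", "ALPHABET", "STRANDS",
                                                "BACKGROUND")):
                continue
            if line.upper().startswith("MOTIF"):
                _flush()
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}: MOTIF line without a name at line {lineno}")
                name = parts[1]
                continue
            if name is None:
                raise ValueError(f"{path}: matrix row before any MOTIF at line {lineno}")
            vals = [float(x) for x in line.split()]
            if len(vals) != 4:
                raise ValueError(f"{path}: expected 4 probabilities at line {lineno}")
            total = sum(vals)
            if not (0.9 <= total <= 1.1):
                raise ValueError(
                    f"{path}: row sum {total:g} at line {lineno} is outside [0.9, 1.1] "
                    "(probabilities expected, not counts)")
            rows.append([v / total for v in vals])
    _flush()
    return motifs


def write_pwm(motifs: Sequence[PWMMotif], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def pwm_from_tsv(path) -> List[PWMMotif]:
    """Convert a 4-column TSV matrix file (motif_id, A, C, G, T) to motifs."""
    df = pd.read_csv(path, sep="\t")
    required = {"motif_id", "A", "C", "G", "T"}
    if not required.issubset(df.columns):
        raise ValueError("TSV PWM needs columns motif_id, A, C, G, T")
    out = []
    for motif_id, grp in df.groupby("motif_id", sort=False):
        mat = grp[["A", "C", "G", "T"]].to_numpy(dtype=float)
        mat = mat / mat.sum(axis=1, keepdims=True)
        out.append(PWMMotif(motif_id=str(motif_id), matrix=mat))
    return out


# ---------------------------------------------------------------------------
# BED / TSV / config
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    if df.shape[1] >= 4:
        cols[3] = "name"
    df.columns = cols
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] < 0).any() or (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: malformed BED intervals")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_config(path_or_dict) -> dict:
    """Load a YAML key-value config file (or pass a dict through)."""
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to values")
    return cfg
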