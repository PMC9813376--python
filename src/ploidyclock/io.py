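"""Readers and writers for the formats the pipeline touches.

Coordinate conventions are fixed here once: VCF positions are 1-based;
segment/BED/bin intervals are 0-based half-open. All table formats are
UTF-8 tab-separated text; gzip is handled transparently by extension.

VCF handling is deliberately minimal: one record per ALT allele, read
evidence taken from the per-sample AD field (ref,alt counts) or, when
AD is absent, from DP+AF. Phasing, multi-sample merging and the rest of
the VCF spec are out of scope.
"""

from __future__ import annotations

import gzip


import os
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import pysam

from .exceptions import FormatError, ValidationError
from .segments import SegmentProfile, make_profile
from .variants import SVBreakpointPair, SVType, VariantRecord

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]
BIN_COLUMNS = ["chrom", "start", "end", "count"]

# breakpoint-end encoding: 3' end of a segment joins as "+", 5' end as "-"
_CT_TO_STRANDS = {"3to3": ("+", "+"), "5to5": ("-", "-"),
                  "3to5": ("+", "-"), "5to3": ("-", "+")}
_STRANDS_TO_CT = {v: k for k, v in _CT_TO_STRANDS.items()}

_SVTYPE_CODE = {
    SVType.DELETION_LIKE: "DEL",
    SVType.DUPLICATION_LIKE: "DUP",
    SVType.INV_HEAD_TO_HEAD: "INV",
    SVType.INV_TAIL_TO_TAIL: "INV",
    SVType.TRANSLOCATION: "TRA",
}


def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8" if "t" in mode else None)
    return open(path, mode, encoding="utf-8")


def _count_header_lines(path) -> int:
    """Lines starting with '#' at the top of a (possibly gzipped) VCF."""
    n = 0
    with _open_text(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
    return n


# ---------------------------------------------------------------------------
# small-variant VCF

def read_vcf_minimal(path, caller_id: str = "") -> list[VariantRecord]:
    """Read a minimal somatic VCF into :class:`VariantRecord` objects.

    One record is emitted per ALT allele of the first sample. Read
    evidence comes from AD when present (preferred: it is the raw
    count evidence), otherwise from DP and AF.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: malformed VCF header or file: {exc}") from exc
    n_header = _count_header_lines(path)
    records: list[VariantRecord] = []
    with vf:
        for i, rec in enumerate(vf):
            line_no = n_header + 1 + i
            try:
                records.extend(_records_from_pysam(rec, caller_id))
            except (ValidationError, FormatError, TypeError, ValueError) as exc:
                raise FormatError(f"{path} line {line_no}: {exc}") from exc
    return records


def _records_from_pysam(rec, caller_id: str) -> list[VariantRecord]:
    alts = rec.alts or ()
    if not rec.samples:
        raise FormatError("no sample column; AD or DP+AF required")
    sample = rec.samples[0]
    ad = sample.get("AD")
    out = []
    for j, alt in enumerate(alts):
        if ad is not None and ad[0] is not None:
            ref_reads = int(ad[0])
            alt_reads = int(ad[j + 1])
            depth = ref_reads + sum(int(a) for a in ad[1:] if a is not None)
        else:
            dp, af = sample.get("DP"), sample.get("AF")
            if dp is None or af is None:
                raise FormatError("sample lacks both AD and DP+AF")
            af_j = af[j] if isinstance(af, (tuple, list)) else af
            depth = int(dp)
            alt_reads = int(round(float(af_j) * depth))
        out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt,
                                 alt_reads, depth, caller_id))
    return out


def write_vcf_minimal(records: Sequence[VariantRecord], path) -> None:
    """Write records as a minimal single-sample VCF (AD/DP evidence).

    Chromosomes are declared in input order; no genome check is done at
    this layer, so records on unknown chromosomes are written verbatim.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    seen = []
    for r in records:
        if r.chrom not in seen:
            seen.append(r.chrom)
    for chrom in seen:
        header.contigs.add(chrom)
    header.add_sample("TUMOR")
    mode = "w" if not str(path).endswith(".gz") else "wz"
    try:
        out = pysam.VariantFile(os.fspath(path), mode, header=header)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    with out:
        for r in sorted(records, key=lambda v: (seen.index(v.chrom), v.pos)):
            rec = out.new_record(contig=r.chrom, start=r.pos - 1,
                                 alleles=(r.ref, r.alt))
            rec.samples["TUMOR"]["AD"] = (r.total_depth - r.alt_reads, r.alt_reads)
            rec.samples["TUMOR"]["DP"] = r.total_depth
            out.write(rec)


# ---------------------------------------------------------------------------
# structural-variant VCF

def read_sv_vcf(path, caller_id: str = "") -> list[SVBreakpointPair]:
    """Read SVs from a VCF using SVTYPE/END/CT INFO fields (Delly-style).

    SVTYPE is DEL/DUP/INV/TRA; CT encodes the joined segment ends
    (``3to3`` head-to-head, ``5to5`` tail-to-tail, ``3to5`` deletion-like,
    ``5to3`` duplication-like). Translocations read the mate chromosome
    from CHR2.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: malformed VCF header or file: {exc}") from exc
    n_header = _count_header_lines(path)
    out: list[SVBreakpointPair] = []
    with vf:
        for i, rec in enumerate(vf):
            line_no = n_header + 1 + i
            try:
                out.append(_sv_from_pysam(rec, caller_id))
            except (KeyError, ValueError, ValidationError) as exc:
                raise FormatError(f"{path} line {line_no}: {exc}") from exc
    return out


def _sv_from_pysam(rec, caller_id: str) -> SVBreakpointPair:
    info = rec.info
    svtype = str(info["SVTYPE"])
    ct = str(info.get("CT", ""))
    if ct not in _CT_TO_STRANDS:
        raise ValueError(f"missing or invalid CT field {ct!r}")
    s1, s2 = _CT_TO_STRANDS[ct]
    if svtype == "TRA":
        chr2 = str(info["CHR2"])
        # htslib clamps END below POS, so translocations carry POS2
        pos2 = int(info["POS2"])
        return SVBreakpointPair(SVType.TRANSLOCATION, (rec.chrom, rec.pos, s1),
                                (chr2, pos2, s2), caller_id)
    end = rec.stop
    if svtype == "DEL":
        sv_type = SVType.DELETION_LIKE
    elif svtype == "DUP":
        sv_type = SVType.DUPLICATION_LIKE
    elif svtype == "INV":
        sv_type = SVType.INV_HEAD_TO_HEAD if ct == "3to3" else SVType.INV_TAIL_TO_TAIL
        if ct not in ("3to3", "5to5"):
            raise ValueError(f"INV requires CT 3to3 or 5to5, got {ct}")
    else:
        raise ValueError(f"unsupported SVTYPE {svtype!r}")
    return SVBreakpointPair(sv_type, (rec.chrom, rec.pos, s1), (rec.chrom, end, s2), caller_id)


def write_sv_vcf(svs: Sequence[SVBreakpointPair], path) -> None:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="Second breakpoint">')
    header.add_line('##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">')
    header.add_line('##INFO=<ID=POS2,Number=1,Type=Integer,Description="Mate position (translocations)">')
    header.add_line('##INFO=<ID=CT,Number=1,Type=String,Description="Joined segment ends">')
    seen = []
    for sv in svs:
        for c in (sv.bp1[0], sv.bp2[0]):
            if c not in seen:
                seen.append(c)
    for chrom in seen:
        header.contigs.add(chrom)
    header.add_sample("TUMOR")
    mode = "w" if not str(path).endswith(".gz") else "wz"
    with pysam.VariantFile(os.fspath(path), mode, header=header) as out:
        for sv in svs:
            intra = sv.sv_type is not SVType.TRANSLOCATION
            rec = out.new_record(contig=sv.bp1[0], start=sv.bp1[1] - 1,
                                 stop=sv.bp2[1] if intra else sv.bp1[1],
                                 alleles=("N", "<SV>"))
            rec.info["SVTYPE"] = _SVTYPE_CODE[sv.sv_type]
            rec.info["CT"] = _STRANDS_TO_CT[sv.strands]
            if not intra:
                rec.info["CHR2"] = sv.bp2[0]
                rec.info["POS2"] = sv.bp2[1]
            out.write(rec)


# ---------------------------------------------------------------------------
# segment and bin tables

def read_segments_tsv(
    path,
    purity: Union[float, Mapping[str, float]] = 1.0,
    genome=None,
) -> dict[str, SegmentProfile]:
    """Read an ASCAT-like segment table into per-sample profiles.

    Columns: sample, chrom, start, end, major_cn, minor_cn (0-based
    half-open intervals). Rows with major < minor are swapped with a
    warning; overlapping rows raise. ``purity`` may be a single value
    or a per-sample mapping (purity is metadata, not part of the table).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse segment TSV: {exc}") from exc
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    profiles: dict[str, SegmentProfile] = {}
    for sample, sub in df.groupby("sample", sort=True):
        rho = purity.get(sample, 1.0) if isinstance(purity, Mapping) else purity
        profiles[sample] = make_profile(
            sample, rho,
            sub[["chrom", "start", "end", "major_cn", "minor_cn"]].itertuples(index=False),
            genome=genome,
        )
    return profiles


def write_segments_tsv(profiles: Union[SegmentProfile, Iterable[SegmentProfile]], path) -> None:
    if isinstance(profiles, SegmentProfile):
        profiles = [profiles]
    rows = [
        (p.sample_id, s.chrom, s.start, s.end, s.major_cn, s.minor_cn)
        for p in profiles for s in p
    ]
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_bins_tsv(path) -> pd.DataFrame:
    """Read a low-pass bin track (chrom, start, end, count) as a DataFrame."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse bin TSV: {exc}") from exc
    missing = [c for c in BIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df["count"] < 0).any():
        raise FormatError(f"{path}: negative bin counts")
    return df[BIN_COLUMNS].copy()


def write_bins_tsv(df: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        df[BIN_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_bed3(path) -> list[tuple[str, int, int]]:
    """Read BED3 loci (0-based half-open)."""
    out = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {i}: expected >=3 BED columns")
            try:
                out.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path} line {i}: {exc}") from exc
    return out
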