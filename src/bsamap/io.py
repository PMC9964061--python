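"""Readers and writers for the formats the pipeline touches.

VCF 4.x with per-sample allele depths (``FORMAT/AD``) is what a
samtools/bcftools calling step emits for the two pools; GFF3 carries the
gene models used for splice-site annotation; a plain 8-column TSV is the
marker-count interchange table used between pipeline stages.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    VALID_BASES,
    DataError,
    GeneModel,
    MarkerTrack,
    SampleNotFoundError,
)

log = logging.getLogger(__name__)

MARKER_TABLE_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "wt_ref",
    "wt_alt",
    "mut_ref",
    "mut_alt",
)


def _is_snp_record(ref: str, alts: Sequence[str]) -> bool:
    if len(alts) != 1:
        return False
    alt = alts[0]
    return len(ref) == 1 and len(alt) == 1 and ref in VALID_BASES and alt in VALID_BASES


def read_pooled_vcf(
    path: str | Path, wt_sample: str, mut_sample: str
) -> dict[str, MarkerTrack]:
    """Read biallelic SNP allele depths for two pools from one VCF.

    Multiallelic and indel records are skipped (the scan is SNP-only);
    records missing the AD field for either pool are skipped with a
    logged warning.  Returns one :class:`MarkerTrack` per chromosome.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (wt_sample, mut_sample):
        if name not in samples:
            raise SampleNotFoundError(
                f"sample {name!r} not in VCF {path} (has {samples})"
            )
    i_wt = samples.index(wt_sample)
    i_mut = samples.index(mut_sample)

    rows: dict[str, list[tuple]] = {}
    n_skipped = 0
    for rec in vcf:
        if not _is_snp_record(rec.REF, rec.ALT):
            continue
        ad = rec.format("AD")
        if ad is None or ad.shape[1] < 2:
            n_skipped += 1
            continue
        wt = ad[i_wt]
        mut = ad[i_mut]
        if min(int(wt[0]), int(wt[1]), int(mut[0]), int(mut[1])) < 0:
            n_skipped += 1  # cyvcf2 encodes missing AD as negative sentinels
            continue
        rows.setdefault(rec.CHROM, []).append(
            (rec.POS, rec.REF, rec.ALT[0], int(wt[0]), int(wt[1]), int(mut[0]), int(mut[1]))
        )
    if n_skipped:
        log.warning("skipped %d records lacking usable FORMAT/AD", n_skipped)

    tracks: dict[str, MarkerTrack] = {}
    for chrom, recs in rows.items():
        recs.sort(key=lambda r: r[0])
        dedup = [r for i, r in enumerate(recs) if i == 0 or r[0] != recs[i - 1][0]]
        if len(dedup) != len(recs):
            log.warning("dropped %d duplicate positions on %s", len(recs) - len(dedup), chrom)
        cols = list(zip(*dedup))
        tracks[chrom] = MarkerTrack(chrom, *cols)
    return tracks


def merge_pool_vcfs(
    wt_path: str | Path,
    wt_sample: str,
    mut_path: str | Path,
    mut_sample: str,
) -> dict[str, MarkerTrack]:
    """Combine two single-sample VCFs (one per pool) into pooled tracks.

    Markers are matched on (chrom, pos, ref, alt); records present in
    only one pool are dropped, since the test needs counts from both.
    """
    wt = read_pooled_vcf(wt_path, wt_sample, wt_sample)
    mut = read_pooled_vcf(mut_path, mut_sample, mut_sample)
    out: dict[str, MarkerTrack] = {}
    for chrom in sorted(set(wt) & set(mut)):
        a, b = wt[chrom], mut[chrom]
        key_a = {(int(p), r, t): i for i, (p, r, t) in enumerate(zip(a.pos, a.ref, a.alt))}
        ia, ib = [], []
        for j, (p, r, t) in enumerate(zip(b.pos, b.ref, b.alt)):
            i = key_a.get((int(p), str(r), str(t)))
            if i is not None:
                ia.append(i)
                ib.append(j)
        if not ia:
            continue
        ia_arr, ib_arr = np.array(ia), np.array(ib)
        out[chrom] = MarkerTrack(
            chrom,
            a.pos[ia_arr],
            a.ref[ia_arr],
            a.alt[ia_arr],
            a.wt_ref[ia_arr],
            a.wt_alt[ia_arr],
            b.mut_ref[ib_arr],
            b.mut_alt[ib_arr],
        )
    return out


def read_control_variants(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Load a control line's variant set as (chrom, pos, ref, alt) keys.

    Accepts a VCF (any biallelic SNP record counts) or a marker TSV.
    Used to exclude polymorphisms shared with sibling mutant lines or
    the non-reference parental accession.
    """
    path = Path(path)
    if path.suffix in (".tsv", ".txt"):
        tracks = read_marker_table(path)
        return {
            (t.chrom, int(p), str(r), str(a))
            for t in tracks.values()
            for p, r, a in zip(t.pos, t.ref, t.alt)
        }
    from cyvcf2 import VCF

    out = set()
    for rec in VCF(str(path)):
        if _is_snp_record(rec.REF, rec.ALT):
            out.add((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    return out


# ---------------------------------------------------------------------------
# marker table (TSV interchange)


def write_marker_table(
    tracks: Mapping[str, MarkerTrack] | Iterable[MarkerTrack], path: str | Path
) -> None:
    """Write tracks as a TSV with the 8 canonical columns."""
    if isinstance(tracks, Mapping):
        tracks = [tracks[k] for k in sorted(tracks)]
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "chrom": t.chrom,
                    "pos": t.pos,
                    "ref": t.ref,
                    "alt": t.alt,
                    "wt_ref": t.wt_ref,
                    "wt_alt": t.wt_alt,
                    "mut_ref": t.mut_ref,
                    "mut_alt": t.mut_alt,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=MARKER_TABLE_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> dict[str, MarkerTrack]:
    """Read a marker TSV back into per-chromosome tracks.

    Malformed rows raise :class:`DataError` naming the offending line
    (1-based, counting the header as line 1).
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "chrom": str,
                "pos": np.int64,
                "ref": str,
                "alt": str,
                "wt_ref": np.int64,
                "wt_alt": np.int64,
                "mut_ref": np.int64,
                "mut_alt": np.int64,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataError(f"malformed marker table {path}: {exc}") from exc
    missing = set(MARKER_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"marker table {path} lacks columns {sorted(missing)}")

    counts = df[["wt_ref", "wt_alt", "mut_ref", "mut_alt"]].to_numpy()
    bad = np.flatnonzero((counts < 0).any(axis=1))
    if bad.size:
        raise DataError(f"negative count at line {int(bad[0]) + 2} of {path}")

    tracks: dict[str, MarkerTrack] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        try:
            tracks[str(chrom)] = MarkerTrack(
                str(chrom),
                sub["pos"].to_numpy(),
                sub["ref"].to_numpy(),
                sub["alt"].to_numpy(),
                sub["wt_ref"].to_numpy(),
                sub["wt_alt"].to_numpy(),
                sub["mut_ref"].to_numpy(),
                sub["mut_alt"].to_numpy(),
            )
        except DataError as exc:
            raise DataError(f"invalid markers in {path}: {exc}") from exc
    return tracks


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Parse gene models (one per mRNA) from a GFF3 file.

    Exons are collected per mRNA/transcript feature; models whose exons
    overlap or cannot be ordered are rejected with a warning rather
    than propagating a broken model into splice-site annotation.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        if not exons:
            continue
        try:
            models.append(
                GeneModel(
                    gene_id=mrna.id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                )
            )
        except DataError as exc:
            log.warning("rejecting gene model %s: %s", mrna.id, exc)
    return models


# ---------------------------------------------------------------------------
# VCF writing (simulator output)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bsamap-simulator
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_pooled_vcf(
    tracks: Mapping[str, MarkerTrack],
    path: str | Path,
    wt_sample: str = "wt_pool",
    mut_sample: str = "mut_pool",
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Serialize pooled marker counts as a two-sample VCF with AD fields."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted(tracks):
            length = (contig_lengths or {}).get(chrom)
            if length:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{wt_sample}\t{mut_sample}\n"
        )
        for chrom in sorted(tracks):
            for m in tracks[chrom]:
                fh.write(
                    f"{m.chrom}\t{m.pos}\t.\t{m.ref}\t{m.alt}\t.\t.\t.\t"
                    f"AD:DP\t{m.wt_ref},{m.wt_alt}:{m.wt_depth}\t"
                    f"{m.mut_ref},{m.mut_alt}:{m.mut_depth}\n"
                )
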