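"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: BED3+ for nucleosome positioning sites
(extra columns ignored, maps are strandless), BED4 for chromatin-state
domains (4th column is the state label), and wide TSV for the gene /
expression table (``gene_id  chrom  tss  strand  rpkm_s2  <tissue...>``).
All coordinates are 0-based half-open.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence

import pandas as pd

from .model import ChromatinDomain, Gene, NucleosomeSite

GENE_TABLE_FIXED_COLUMNS = ["gene_id", "chrom", "tss", "strand", "rpkm_s2"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def read_gene_table(path: str | os.PathLike) -> list[Gene]:
    """Read a tab-separated gene/expression table.

    The header must name ``gene_id, chrom, tss, strand, rpkm_s2`` followed by
    one column per tissue (any names; column order defines the tissue order).
    Returns one :class:`Gene` per data row, in file order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in GENE_TABLE_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    tissue_cols = [c for c in df.columns if c not in GENE_TABLE_FIXED_COLUMNS]
    genes: list[Gene] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header line
        rec = dict(zip(df.columns, row))
        gid = str(rec["gene_id"])
        if gid in seen:
            raise FormatError(f"{path}:{line}: duplicate gene_id {gid!r}")
        seen.add(gid)
        strand = str(rec["strand"])
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{line}: invalid strand {strand!r}")
        try:
            tss = int(rec["tss"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{line}: non-integer tss {rec['tss']!r}") from exc
        rpkm = float(rec["rpkm_s2"])
        tissues = tuple(float(rec[c]) for c in tissue_cols)
        if rpkm < 0 or any(v < 0 for v in tissues):
            raise FormatError(f"{path}:{line}: negative RPKM value")
        if tss < 0:
            raise FormatError(f"{path}:{line}: negative tss")
        genes.append(
            Gene(
                gene_id=gid,
                chrom=str(rec["chrom"]),
                tss=tss,
                strand=strand,
                rpkm_s2=rpkm,
                rpkm_tissues=tissues,
            )
        )
    return genes


def write_gene_table(
    genes: Sequence[Gene], path: str | os.PathLike, tissue_names: Sequence[str] | None = None
) -> None:
    """Write a gene table readable by :func:`read_gene_table`."""
    n_tissues = len(genes[0].rpkm_tissues) if genes else 0
    if tissue_names is None:
        tissue_names = [f"tissue_{i + 1:02d}" for i in range(n_tissues)]
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "tss": g.tss,
            "strand": g.strand,
            "rpkm_s2": g.rpkm_s2,
            **dict(zip(tissue_names, g.rpkm_tissues)),
        }
        for g in genes
    ]
    df = pd.DataFrame(rows, columns=GENE_TABLE_FIXED_COLUMNS + list(tissue_names))
    write_table(df, path)


def _parse_bed_coords(path, line_no: int, fields: list[str]):
    if len(fields) < 3:
        raise FormatError(f"{path}:{line_no}: expected at least 3 BED columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(
            f"{path}:{line_no}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
        ) from exc
    if start >= end or start < 0:
        raise FormatError(f"{path}:{line_no}: invalid interval [{start}, {end})")
    return fields[0], start, end


def read_bed_sites(path: str | os.PathLike, sensitivity: str) -> list[NucleosomeSite]:
    """Read nucleosome positioning sites from a BED3+ file.

    Columns beyond the third (name, score, strand, ...) are ignored; the
    sensitivity class is a property of the whole file, one file per class.
    """
    sites: list[NucleosomeSite] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = _parse_bed_coords(path, line_no, line.split("\t"))
            sites.append(NucleosomeSite(chrom, start, end, sensitivity))
    return sites


def read_bed_sites_frame(path: str | os.PathLike, sensitivity: str) -> pd.DataFrame:
    """Vectorised BED3+ site reader returning a chrom/start/end table.

    Semantically equivalent to :func:`read_bed_sites` but suitable for
    maps with millions of sites; extra columns are dropped.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": "int64", "end": "int64"},
        )
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer coordinates ({exc})") from exc
    invalid = (df["start"] >= df["end"]) | (df["start"] < 0)
    if invalid.any():
        line = int(df.index[invalid][0]) + 1
        raise FormatError(f"{path}:{line}: invalid interval")
    df["sensitivity"] = sensitivity
    return df


def write_bed_sites(sites: Iterable[NucleosomeSite], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\n")


def normalize_domains(domains: Iterable[ChromatinDomain]) -> list[ChromatinDomain]:
    """Sort domains per chromosome and merge touching/overlapping same-state runs.

    Overlapping intervals with *different* states are a contract violation.
    The operation is idempotent.
    """
    by_chrom: dict[str, list[ChromatinDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    out: list[ChromatinDomain] = []
    for chrom in sorted(by_chrom):
        merged: list[ChromatinDomain] = []
        for d in sorted(by_chrom[chrom], key=lambda d: (d.start, d.end)):
            if merged and d.start < merged[-1].end and d.state != merged[-1].state:
                raise FormatError(
                    f"overlapping domains with different states on {chrom}: "
                    f"[{merged[-1].start}, {merged[-1].end}) {merged[-1].state} vs "
                    f"[{d.start}, {d.end}) {d.state}"
                )
            if merged and d.start <= merged[-1].end and d.state == merged[-1].state:
                prev = merged.pop()
                d = ChromatinDomain(chrom, prev.start, max(prev.end, d.end), d.state)
            merged.append(d)
        out.extend(merged)
    return out


def read_bed_domains(
    path: str | os.PathLike, alphabet: frozenset[str] | set[str]
) -> list[ChromatinDomain]:
    """Read chromatin-state domains from a BED4 file and normalize them.

    The 4th column must be a label from ``alphabet``; same-state adjacent
    intervals are merged on load.
    """
    domains: list[ChromatinDomain] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = _parse_bed_coords(path, line_no, fields)
            if len(fields) < 4:
                raise FormatError(f"{path}:{line_no}: missing state label column")
            state = fields[3]
            if state not in alphabet:
                raise FormatError(
                    f"{path}:{line_no}: unknown state {state!r}; "
                    f"allowed: {sorted(alphabet)}"
                )
            domains.append(ChromatinDomain(chrom, start, end, state))
    return normalize_domains(domains)


def write_bed_domains(domains: Iterable[ChromatinDomain], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.state}\n")


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as TSV with floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
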