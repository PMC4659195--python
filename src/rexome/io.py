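"""Readers and writers for the plain-text formats the pipeline consumes.

Formats
-------
* BED (3+ columns, 0-based half-open) for target and exon intervals.
* samtools-depth-style TSV: ``chrom <TAB> 1-based position <TAB> depth``.
  On write, every target base is emitted (zeros included) so that files
  over the same target space are alignment-free comparable.
* 6-column PED for pedigrees (family, individual, father, mother, sex,
  phenotype); the phenotype column is ignored.
* VCF-lite genotype TSV with header
  ``#chrom pos ref alt sample replicate genotype depth quality``
  (pos is 1-based on disk, 0-based in memory).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GT_COLUMNS,
    DepthProfile,
    Pedigree,
    TargetRegions,
    validate_genotype_table,
)

GT_HEADER = "#" + "\t".join(GT_COLUMNS)


class ParseError(ValueError):
    """A malformed line in an input file; carries the line number."""


def read_bed(path) -> TargetRegions:
    """Read a 3+ column BED file into merged, sorted :class:`TargetRegions`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            intervals.append((fields[0], start, end))
    if not intervals:
        raise ParseError(f"{path}: no intervals")
    return TargetRegions(intervals)


def write_bed(intervals, path) -> None:
    """Write intervals (``TargetRegions`` or (chrom, start, end) iterable)."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_depth_table(
    path,
    targets: TargetRegions,
    sample_id: str = "",
    replicate_id: str = "",
    strict: bool = False,
) -> DepthProfile:
    """Read a samtools-depth-style TSV into a dense :class:`DepthProfile`.

    Positions in the file are 1-based; positions inside *targets* but absent
    from the file get depth 0.  Off-target positions raise when *strict*,
    otherwise they are skipped with a warning.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "pos", "depth"],
        dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
    )
    if len(df) and (df["depth"] < 0).any():
        bad = df.index[df["depth"] < 0][0] + 1
        raise ValueError(f"{path}: negative depth at data row {bad}")
    depth = np.zeros(targets.total_bases, dtype=np.int64)
    if len(df):
        flat = targets.locate_table(df["chrom"].to_numpy(), df["pos"].to_numpy() - 1)
        off = flat < 0
        if off.any():
            n = int(off.sum())
            if strict:
                i = int(np.flatnonzero(off)[0])
                raise ValueError(
                    f"{path}: position {df['chrom'].iat[i]}:{df['pos'].iat[i]} "
                    f"outside target space ({n} off-target rows)"
                )
            warnings.warn(
                f"{path}: skipped {n} off-target position(s)", stacklevel=2
            )
            flat = flat[~off]
            df = df.loc[~off]
        depth[flat] = df["depth"].to_numpy()
    return DepthProfile(targets, depth, sample_id, replicate_id)


def write_depth_table(profile: DepthProfile, path) -> None:
    """Write a dense depth TSV (1-based positions, zeros emitted)."""
    t = profile.targets
    chroms = np.repeat(np.asarray(t.chroms, dtype=object), t.lengths)
    pos = np.concatenate(
        [np.arange(s + 1, e + 1, dtype=np.int64) for s, e in zip(t.starts, t.ends)]
    )
    pd.DataFrame({"chrom": chroms, "pos": pos, "depth": profile.depth}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_pedigree(path) -> Pedigree:
    """Read a 6-column PED file (affection column ignored)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=5 whitespace-"
                    f"separated PED columns, got {len(fields)}"
                )
            _fam, iid, father, mother, sex = fields[:5]
            records.append((iid, father, mother, int(sex)))
    return Pedigree(records)


def write_pedigree(pedigree: Pedigree, path, family_id: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for iid in pedigree.topological_order():
            ind = pedigree.individuals[iid]
            fh.write(
                f"{family_id}\t{iid}\t{ind.father or 0}\t{ind.mother or 0}"
                f"\t{ind.sex}\t0\n"
            )


AC_COLUMNS = ("chrom", "pos", "ref", "alt", "sample", "replicate",
              "ref_count", "alt_count")
AC_HEADER = "#" + "\t".join(AC_COLUMNS)


def read_allele_counts(path) -> pd.DataFrame:
    """Read a per-site allele-count TSV (pos 1-based on disk)."""
    df = pd.read_csv(
        path, sep="\t", header=0,
        dtype={"#chrom": str, "ref": str, "alt": str,
               "sample": str, "replicate": str},
    )
    df = df.rename(columns={"#chrom": "chrom"})
    missing = [c for c in AC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: allele-count table missing columns {missing}")
    df["pos"] = df["pos"].astype(np.int64) - 1
    for c in ("ref_count", "alt_count"):
        df[c] = df[c].astype(np.int64)
        if (df[c] < 0).any():
            raise ValueError(f"{path}: negative {c}")
    return df.loc[:, list(AC_COLUMNS)]


def write_allele_counts(df: pd.DataFrame, path) -> None:
    out = df.loc[:, list(AC_COLUMNS)].copy()
    out["pos"] = out["pos"] + 1
    with open(path, "w") as fh:
        fh.write(AC_HEADER + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_genotype_table(path) -> pd.DataFrame:
    """Read the VCF-lite genotype TSV (pos 1-based on disk)."""
    df = pd.read_csv(
        path, sep="\t", header=0,
        dtype={"#chrom": str, "ref": str, "alt": str,
               "sample": str, "replicate": str, "genotype": str},
    )
    df = df.rename(columns={"#chrom": "chrom"})
    df["pos"] = df["pos"].astype(np.int64) - 1
    return validate_genotype_table(df)


def write_genotype_table(df: pd.DataFrame, path) -> None:
    df = validate_genotype_table(df)
    out = df.copy()
    out["pos"] = out["pos"] + 1
    with open(path, "w") as fh:
        fh.write(GT_HEADER + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)
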