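"""Core genomic containers: target regions, per-base depth, pedigrees, genotype tables.

All coordinates are 0-based half-open internally.  File readers/writers in
:mod:`rexome.io` convert at the boundary (BED is native, samtools-style depth
tables and the genotype TSV are 1-based on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

GENOTYPE_STATES = ("hom_ref", "het", "hom_alt")
NO_CALL = "no_call"
GENOTYPE_TOKENS = GENOTYPE_STATES + (NO_CALL,)

#: canonical column order of a genotype table (a plain pandas DataFrame)
GT_COLUMNS = (
    "chrom", "pos", "ref", "alt", "sample", "replicate",
    "genotype", "depth", "quality",
)


class TargetRegions:
    """Merged, sorted genomic intervals with a dense per-base index.

    Intervals are 0-based half-open.  Overlapping or book-ended input
    intervals are merged on construction (capture kits ship overlapping
    probes), so the stored intervals are disjoint and sorted by
    ``(chrom, start)``.

    Every per-base quantity downstream (depth vectors, coverage masks) is a
    dense array of length ``total_bases`` in interval order; :meth:`locate`
    maps genomic ``(chrom, position)`` pairs into that flat index and
    :meth:`flat_to_genomic` maps back.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        ivs: list[tuple[str, int, int]] = []
        for chrom, start, end in intervals:
            s, e = int(start), int(end)
            if s < 0:
                raise ValueError(f"negative interval start: {chrom}:{s}-{e}")
            if s >= e:
                raise ValueError(f"empty or inverted interval: {chrom}:{s}-{e}")
            ivs.append((str(chrom), s, e))
        if not ivs:
            raise ValueError("TargetRegions requires at least one interval")
        ivs.sort()
        merged: list[list] = [list(ivs[0])]
        for c, s, e in ivs[1:]:
            last = merged[-1]
            if c == last[0] and s <= last[2]:
                last[2] = max(last[2], e)
            else:
                merged.append([c, s, e])
        self.chroms: tuple[str, ...] = tuple(c for c, _, _ in merged)
        self.starts: np.ndarray = np.array([s for _, s, _ in merged], dtype=np.int64)
        self.ends: np.ndarray = np.array([e for _, _, e in merged], dtype=np.int64)
        lengths = self.ends - self.starts
        self.offsets: np.ndarray = np.concatenate([[0], np.cumsum(lengths)])
        self.total_bases: int = int(self.offsets[-1])
        # per-chrom slices for vectorised locate(); intervals of one chrom
        # are contiguous in the sorted order
        self._chrom_slice: dict[str, slice] = {}
        i = 0
        for j in range(1, len(self.chroms) + 1):
            if j == len(self.chroms) or self.chroms[j] != self.chroms[i]:
                self._chrom_slice[self.chroms[i]] = slice(i, j)
                i = j

    # ------------------------------------------------------------------
    @property
    def n_intervals(self) -> int:
        return len(self.chroms)

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (c, int(s), int(e))
            for c, s, e in zip(self.chroms, self.starts, self.ends)
        ]

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def __len__(self) -> int:
        return self.n_intervals

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetRegions):
            return NotImplemented
        return (
            self.chroms == other.chroms
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def __repr__(self) -> str:
        return (
            f"TargetRegions({self.n_intervals} intervals, "
            f"{self.total_bases} bases)"
        )

    # ------------------------------------------------------------------
    def locate(self, chrom: str, positions) -> np.ndarray:
        """Map 0-based genomic positions on *chrom* to flat indices.

        Positions outside every interval map to -1.
        """
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        out = np.full(positions.shape, -1, dtype=np.int64)
        sl = self._chrom_slice.get(str(chrom))
        if sl is None:
            return out
        starts, ends = self.starts[sl], self.ends[sl]
        offs = self.offsets[sl.start:sl.stop]
        j = np.searchsorted(starts, positions, side="right") - 1
        jj = np.clip(j, 0, None)
        ok = (j >= 0) & (positions < ends[jj])
        out[ok] = offs[jj[ok]] + positions[ok] - starts[jj[ok]]
        return out

    def locate_table(self, chroms: Sequence[str], positions) -> np.ndarray:
        """Vectorised :meth:`locate` for per-row (chrom, pos) pairs."""
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, -1, dtype=np.int64)
        for c in np.unique(chroms):
            m = chroms == c
            out[m] = self.locate(c, positions[m])
        return out

    def interval_index(self, flat) -> np.ndarray:
        """Index of the interval containing each flat position."""
        flat = np.asarray(flat, dtype=np.int64)
        return np.searchsorted(self.offsets, flat, side="right") - 1

    def flat_to_genomic(self, flat) -> tuple[np.ndarray, np.ndarray]:
        """Map flat indices back to (chrom, 0-based position) arrays."""
        flat = np.atleast_1d(np.asarray(flat, dtype=np.int64))
        if flat.size and (flat.min() < 0 or flat.max() >= self.total_bases):
            raise IndexError("flat index outside target space")
        i = self.interval_index(flat)
        pos = self.starts[i] + (flat - self.offsets[i])
        chroms = np.array([self.chroms[k] for k in i], dtype=object)
        return chroms, pos


@dataclass
class DepthProfile:
    """Per-base sequencing depth over a target space for one library.

    ``depth[i]`` is the Q20-filtered depth at flat position ``i`` of
    ``targets``; ``replicate_id`` is a library label or ``"aggregate"`` for
    the per-individual merge of all technical replicates.
    """

    targets: TargetRegions
    depth: np.ndarray
    sample_id: str
    replicate_id: str

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.shape != (self.targets.total_bases,):
            raise ValueError(
                f"depth vector length {self.depth.shape} does not match "
                f"target space of {self.targets.total_bases} bases"
            )
        if not np.issubdtype(self.depth.dtype, np.integer):
            if not np.array_equal(self.depth, self.depth.astype(np.int64)):
                raise ValueError("depths must be integers")
        self.depth = self.depth.astype(np.int64)
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("negative depth")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthProfile):
            return NotImplemented
        return (
            self.targets == other.targets
            and np.array_equal(self.depth, other.depth)
            and self.sample_id == other.sample_id
            and self.replicate_id == other.replicate_id
        )


# ----------------------------------------------------------------------
# Pedigree
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: int  # 1=male, 2=female, 0=unknown

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass(frozen=True)
class Trio:
    child: str
    father: str
    mother: str


class Pedigree:
    """A validated pedigree with trio enumeration.

    Raises on unknown parent ids and on ancestry cycles.  Trios are every
    child whose father *and* mother are both present, in sorted child order
    (deterministic regardless of input order).
    """

    def __init__(self, records: Iterable[tuple[str, str | None, str | None, int]]):
        self.individuals: dict[str, Individual] = {}
        for iid, father, mother, sex in records:
            iid = str(iid)
            if iid in self.individuals:
                raise ValueError(f"duplicate individual id {iid!r}")
            self.individuals[iid] = Individual(
                iid,
                None if father in (None, "0", "") else str(father),
                None if mother in (None, "0", "") else str(mother),
                int(sex),
            )
        for ind in self.individuals.values():
            for pid in (ind.father, ind.mother):
                if pid is not None and pid not in self.individuals:
                    raise ValueError(
                        f"individual {ind.iid!r} names unknown parent {pid!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValueError(f"pedigree cycle involving {iid!r}")
            state[iid] = 0
            ind = self.individuals[iid]
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1

        for iid in self.individuals:
            visit(iid, [])

    # ------------------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return sorted(self.individuals)

    def founders(self) -> list[str]:
        return [i for i in self.ids if self.individuals[i].is_founder]

    def trios(self) -> list[Trio]:
        out = []
        for iid in self.ids:
            ind = self.individuals[iid]
            if ind.father is not None and ind.mother is not None:
                out.append(Trio(iid, ind.father, ind.mother))
        return out

    def topological_order(self) -> list[str]:
        """Individuals ordered so every parent precedes its children."""
        order: list[str] = []
        done: set[str] = set()

        def visit(iid: str) -> None:
            if iid in done:
                return
            ind = self.individuals[iid]
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    visit(pid)
            done.add(iid)
            order.append(iid)

        for iid in self.ids:
            visit(iid)
        return order

    def __len__(self) -> int:
        return len(self.individuals)


# ----------------------------------------------------------------------
# Genotype tables
# ----------------------------------------------------------------------

def validate_genotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a genotype table DataFrame and normalise dtypes.

    One row per (site, sample, replicate); duplicates are an error, as are
    unknown genotype tokens, negative depths and negative qualities.
    """
    missing = [c for c in GT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")
    df = df.loc[:, list(GT_COLUMNS)].copy()
    bad = set(df["genotype"].unique()) - set(GENOTYPE_TOKENS)
    if bad:
        raise ValueError(f"unknown genotype tokens: {sorted(bad)}")
    df["pos"] = df["pos"].astype(np.int64)
    df["depth"] = df["depth"].astype(np.int64)
    df["quality"] = df["quality"].astype(float)
    if (df["depth"] < 0).any():
        raise ValueError("negative depth in genotype table")
    if (df["quality"] < 0).any():
        raise ValueError("negative quality in genotype table")
    key = ["chrom", "pos", "sample", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = df.loc[dup.idxmax(), key].tolist()
        raise ValueError(f"duplicate (site, sample, replicate) row: {row}")
    return df
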