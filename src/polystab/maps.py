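"""Linkage maps: locus placement, Haldane recombination fractions, and the
harmonic-mean recombination rates that control the strength of Bulmer LD.

A :class:`LinkageMap` assigns each causal locus a chromosome and a genetic
position in Morgans.  Pairwise recombination fractions are 1/2 between
chromosomes and Haldane's function of the Morgan distance within one
(no crossover interference).  The global harmonic mean ``rbar_h`` and the
per-locus harmonic means ``rbar_h(l)`` summarize the map for the analytic
predictors; both are undefined if any pair has ``r = 0``, which is why loci
are never placed at coincident positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import numpy.typing as npt
import pandas as pd

__all__ = [
    "haldane",
    "ChromosomeTable",
    "LinkageMap",
    "place_loci",
    "load_locus_map",
    "unlinked_map",
]


def haldane(d):
    """Haldane's map function r(d) = (1 - exp(-2d))/2, Morgans -> recombination
    fraction.  Strictly increasing from 0, asymptote 1/2 (no interference)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class ChromosomeTable:
    """Per-chromosome physical (bp) and genetic (cM) lengths.

    When sex-specific genetic lengths are supplied, the sex-averaged length
    ``(female + male)/2`` is what all downstream code uses.
    """

    ids: tuple[str, ...]
    bp_lengths: npt.NDArray[np.float64]
    cM_lengths: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp_lengths, dtype=float)
        cm = np.asarray(self.cM_lengths, dtype=float)
        if not (len(self.ids) == bp.size == cm.size):
            raise ValueError("ids, bp_lengths, cM_lengths must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("chromosome ids must be unique")
        if np.any(bp <= 0.0):
            raise ValueError("physical lengths must be positive")
        if np.any(cm < 0.0):
            raise ValueError("genetic lengths must be non-negative")
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "bp_lengths", bp)
        object.__setattr__(self, "cM_lengths", cm)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromosomeTable":
        """Read a TSV with header ``chrom, bp_length, cM_length`` (or
        ``cM_female``/``cM_male``, which are sex-averaged)."""
        df = pd.read_csv(path, sep="\t")
        cols = set(df.columns)
        if not {"chrom", "bp_length"} <= cols:
            raise ValueError(f"{path}: need columns 'chrom' and 'bp_length'")
        if "cM_length" in cols:
            cm = df["cM_length"].to_numpy(float)
        elif {"cM_female", "cM_male"} <= cols:
            cm = (df["cM_female"].to_numpy(float) + df["cM_male"].to_numpy(float)) / 2.0
        else:
            raise ValueError(f"{path}: need 'cM_length' or 'cM_female'+'cM_male'")
        return cls(tuple(df["chrom"].astype(str)), df["bp_length"].to_numpy(float), cm)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"chrom": self.ids, "bp_length": self.bp_lengths, "cM_length": self.cM_lengths}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LinkageMap:
    """Per-locus chromosome assignment and genetic position in Morgans."""

    chrom: tuple[str, ...]
    positions: npt.NDArray[np.float64]  # Morgans
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if len(self.chrom) != pos.size or pos.size < 1:
            raise ValueError("chrom and positions must have equal, positive length")
        seen = set()
        for c, x in zip(self.chrom, pos):
            key = (c, float(x))
            if key in seen:
                raise ValueError(f"coincident loci at chromosome {c}, position {x} M")
            seen.add(key)
        object.__setattr__(self, "chrom", tuple(str(c) for c in self.chrom))
        object.__setattr__(self, "positions", pos)

    @property
    def locus_count(self) -> int:
        return self.positions.size

    def pairwise_r(self, l: int, lprime: int) -> float:
        """Recombination fraction between two loci: 1/2 across chromosomes,
        Haldane of the Morgan distance within one."""
        if self.chrom[l] != self.chrom[lprime]:
            return 0.5
        return haldane(abs(self.positions[l] - self.positions[lprime]))

    def pairwise_r_matrix(self) -> npt.NDArray[np.float64]:
        """Full L x L recombination-fraction matrix (diagonal set to 0)."""
        if "R" not in self._cache:
            pos = self.positions
            chrom = np.asarray(self.chrom)
            same = chrom[:, None] == chrom[None, :]
            R = np.where(same, haldane(np.abs(pos[:, None] - pos[None, :])), 0.5)
            np.fill_diagonal(R, 0.0)
            self._cache["R"] = R
        return self._cache["R"]

    def rbar_h(self) -> float:
        """Global harmonic-mean recombination rate,
        L(L-1) / sum over ordered pairs of 1/r_ll'."""
        return float(self.locus_count * (self.locus_count - 1) / self._inv_r_row_sums().sum())

    def rbar_h_per_locus(self) -> npt.NDArray[np.float64]:
        """Per-locus harmonic means rbar_h(l) = (L-1) / sum_{l'!=l} 1/r_ll'."""
        return (self.locus_count - 1) / self._inv_r_row_sums()

    def _inv_r_row_sums(self) -> npt.NDArray[np.float64]:
        if self.locus_count < 2:
            raise ValueError("harmonic means need at least two loci")
        R = self.pairwise_r_matrix()
        off = R[~np.eye(self.locus_count, dtype=bool)].reshape(self.locus_count, -1)
        if np.any(off == 0.0):
            raise ValueError("zero recombination fraction: harmonic mean undefined")
        return (1.0 / off).sum(axis=1)

    def summary(self):
        """MapSummary (rbar_h, rbar_h(l)) for the equilibrium predictors."""
        from .predictors import MapSummary

        return MapSummary(rbar_h=self.rbar_h(), rbar_h_l=self.rbar_h_per_locus())

    def adjacent_r(self) -> npt.NDArray[np.float64]:
        """Length L-1 vector of recombination fractions between consecutive
        loci in map order, with 1/2 at chromosome boundaries — the gamete
        sampler's per-interval template-switch probabilities."""
        order = self.order()
        pos = self.positions[order]
        chrom = np.asarray(self.chrom)[order]
        gaps = haldane(np.abs(np.diff(pos)))
        same = chrom[:-1] == chrom[1:]
        return np.where(same, gaps, 0.5)

    def order(self) -> npt.NDArray[np.intp]:
        """Locus indices sorted by (chromosome, position)."""
        chrom = np.asarray(self.chrom)
        return np.lexsort((self.positions, chrom))


def unlinked_map(L: int) -> LinkageMap:
    """L loci on L separate chromosomes: every pair recombines freely."""
    return LinkageMap(tuple(f"chr{i + 1}" for i in range(L)), np.zeros(L))


def place_loci(table: ChromosomeTable, L: int) -> LinkageMap:
    """Place ``L`` loci on a chromosome table: counts apportioned proportional
    to physical length (largest-remainder rounding, ties broken by table
    order), then each chromosome's k loci spaced at midpoints
    ``(i - 1/2) * length/k`` of its genetic length — uniform gaps, no loci at
    shared endpoints, so adjacent recombination fractions are positive.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    weights = table.bp_lengths / table.bp_lengths.sum()
    quota = L * weights
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = L - counts.sum()
    if short > 0:
        # stable sort on -remainder preserves table order among ties
        for idx in np.argsort(-remainder, kind="stable")[:short]:
            counts[idx] += 1
    chroms: list[str] = []
    positions: list[float] = []
    for cid, k, cm in zip(table.ids, counts, table.cM_lengths):
        if k == 0:
            continue
        if cm <= 0.0:
            raise ValueError(
                f"chromosome {cid} received {k} loci but has zero genetic length"
            )
        morgans = cm / 100.0
        step = morgans / k
        for i in range(1, k + 1):
            chroms.append(cid)
            positions.append((i - 0.5) * step)
    return LinkageMap(tuple(chroms), np.array(positions))


def load_locus_map(path: str | Path) -> LinkageMap:
    """Load a per-locus map in a PLINK-.map-like dialect: whitespace-separated
    ``chrom  locus_id  cM  [bp]`` per line (the bp column is ignored).
    Positions are converted cM -> Morgans; blank lines and ``#`` comments are
    allowed; malformed lines and coincident positions raise with the line
    number."""
    chroms: list[str] = []
    positions: list[float] = []
    seen: set[tuple[str, float]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) not in (3, 4):
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 4 whitespace-separated fields"
                )
            chrom = fields[0]
            try:
                cm = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: cM position not numeric") from exc
            if not np.isfinite(cm) or cm < 0.0:
                raise ValueError(f"{path}:{lineno}: cM position must be finite and >= 0")
            key = (chrom, cm / 100.0)
            if key in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate position {cm} cM on chromosome {chrom}"
                )
            seen.add(key)
            chroms.append(chrom)
            positions.append(cm / 100.0)
    if not chroms:
        raise ValueError(f"{path}: no loci found")
    return LinkageMap(tuple(chroms), np.array(positions))
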