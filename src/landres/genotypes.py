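"""Multilocus diploid genotypes: data model, GENEPOP I/O, Bray-Curtis distance.

The genetic distance between two individuals is the Bray-Curtis dissimilarity
of their allele-abundance profiles: every (locus, allele) pair observed in the
table is a slot, and an individual's abundance in a slot is the number of
copies carried (0, 1, or 2).  Loci missing in either member of a pair are
dropped pairwise, so each pair's totals equal 4 x (shared loci) and the
dissimilarity lives on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EncodingError, LandresError, ParseError
from .pairwise import PairwiseMatrix

MISSING = 0  # allele code 0 encodes a missing call

SEXES = ("M", "F", "unknown")


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls, with sex and grid location.

    ``calls[i, l]`` holds the unordered diploid pair of positive integer
    allele codes for individual ``i`` at locus ``l``; ``(0, 0)`` means
    missing.  ``location[i]`` is the 0-based ``(row, col)`` grid cell.
    """

    ids: list[str]
    loci: list[str]
    calls: np.ndarray  # (n, n_loci, 2) int
    sex: list[str] = field(default_factory=list)
    location: list[tuple[int, int] | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != len(self.ids):
            raise ConfigurationError("individual ids must be unique")
        self.calls = np.asarray(self.calls, dtype=int)
        if self.calls.size == 0:
            self.calls = self.calls.reshape(len(self.ids), len(self.loci), 2)
        if self.calls.shape != (len(self.ids), len(self.loci), 2):
            raise ConfigurationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        if (self.calls < 0).any():
            raise ConfigurationError("allele codes must be positive (0 = missing)")
        if not self.sex:
            self.sex = ["unknown"] * len(self.ids)
        if not self.location:
            self.location = [None] * len(self.ids)
        for s in self.sex:
            if s not in SEXES:
                raise ConfigurationError(f"sex must be one of {SEXES}, got {s!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci): True where the call is missing."""
        return (self.calls == MISSING).any(axis=2)

    def index_of(self, individual: str) -> int:
        try:
            return self.ids.index(str(individual))
        except ValueError:
            raise LandresError(f"unknown individual: {individual!r}") from None

    def subset(self, keep: Sequence[int]) -> "GenotypeTable":
        keep = list(keep)
        return GenotypeTable(
            ids=[self.ids[i] for i in keep],
            loci=list(self.loci),
            calls=self.calls[keep],
            sex=[self.sex[i] for i in keep],
            location=[self.location[i] for i in keep],
        )

    def drop_loci(self, exclude: Iterable[str]) -> "GenotypeTable":
        exclude = set(exclude)
        keep = [l for l in self.loci if l not in exclude]
        idx = [self.loci.index(l) for l in keep]
        return GenotypeTable(
            ids=list(self.ids),
            loci=keep,
            calls=self.calls[:, idx, :],
            sex=list(self.sex),
            location=list(self.location),
        )


class GeneticDistanceMatrix(PairwiseMatrix):
    """Pairwise Bray-Curtis genetic distance; role tag ``"G"``."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.role = "G"
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ConfigurationError("Bray-Curtis values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# GENEPOP I/O
# ---------------------------------------------------------------------------

def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a GENEPOP file (2- or 3-digit allele encoding).

    Populations are concatenated; the individual id is the token before the
    comma.  ``00``/``000`` alleles decode as missing.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].split(","):
            if name.strip():
                loci.append(name.strip())
        i += 1
    if not loci:
        raise ParseError(f"{path}: no loci declared before first POP")
    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            i += 1
            continue
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}:{i + 1}: expected 'id , genotypes', got {line!r}")
        ind_id, _, geno = line.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"{path}:{i + 1}: {len(tokens)} genotype tokens for "
                f"{len(loci)} loci"
            )
        calls = []
        for tok in tokens:
            if len(tok) == 4:
                width = 2
            elif len(tok) == 6:
                width = 3
            else:
                raise ParseError(
                    f"{path}:{i + 1}: genotype token {tok!r} is neither 4 nor "
                    "6 digits"
                )
            try:
                a, b = int(tok[:width]), int(tok[width:])
            except ValueError:
                raise ParseError(f"{path}:{i + 1}: non-numeric token {tok!r}") from None
            if a == 0 or b == 0:
                a = b = MISSING
            calls.append((a, b))
        ids.append(ind_id.strip())
        rows.append(calls)
        i += 1
    if not ids:
        raise ParseError(f"{path}: no individuals found")
    return GenotypeTable(ids=ids, loci=loci, calls=np.array(rows, dtype=int))


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "landres export") -> None:
    """Write ``table`` in 3-digit GENEPOP encoding (missing as ``000000``)."""
    if table.n_loci == 0:
        raise EncodingError("cannot write a GENEPOP file with zero loci")
    if (table.calls > 999).any():
        raise EncodingError("allele codes > 999 cannot use 3-digit GENEPOP encoding")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        fh.write("POP\n")
        for i, ind in enumerate(table.ids):
            toks = [f"{a:03d}{b:03d}" for a, b in table.calls[i]]
            fh.write(f"{ind} , " + " ".join(toks) + "\n")


def read_locations_csv(path: str | Path) -> pd.DataFrame:
    """Read per-individual grid coordinates and sex (columns id,row,col,sex)."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "row", "col", "sex"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: locations CSV needs columns {sorted(required)}")
    return df


def write_locations_csv(table: GenotypeTable, path: str | Path) -> None:
    rows = []
    for i, ind in enumerate(table.ids):
        loc = table.location[i]
        if loc is None:
            raise EncodingError(f"individual {ind} has no grid location")
        rows.append({"id": ind, "row": loc[0], "col": loc[1], "sex": table.sex[i]})
    pd.DataFrame(rows).to_csv(path, index=False)


def attach_locations(table: GenotypeTable, df: pd.DataFrame) -> GenotypeTable:
    """Return a copy of ``table`` with sex/location taken from a locations frame."""
    by_id = df.set_index(df["id"].astype(str))
    sex, loc = [], []
    for ind in table.ids:
        if ind not in by_id.index:
            raise LandresError(f"individual {ind} missing from locations table")
        rec = by_id.loc[ind]
        sex.append(str(rec["sex"]) if str(rec["sex"]) in SEXES else "unknown")
        loc.append((int(rec["row"]), int(rec["col"])))
    return GenotypeTable(
        ids=list(table.ids), loci=list(table.loci), calls=table.calls.copy(),
        sex=sex, location=loc,
    )


# ---------------------------------------------------------------------------
# Allele abundance & Bray-Curtis
# ---------------------------------------------------------------------------

def allele_slots(table: GenotypeTable, loci_subset: Sequence[str] | None = None
                 ) -> list[tuple[str, int]]:
    """Ordered (locus, allele) slots observed anywhere in the table."""
    loci = list(loci_subset) if loci_subset is not None else list(table.loci)
    if not loci:
        raise ConfigurationError("loci subset must be non-empty")
    slots: list[tuple[str, int]] = []
    for locus in loci:
        l = table.loci.index(locus)
        alleles = np.unique(table.calls[:, l, :])
        for a in alleles:
            if a != MISSING:
                slots.append((locus, int(a)))
    return slots


def allele_abundance(table: GenotypeTable, individual: str,
                     loci_subset: Sequence[str] | None = None) -> np.ndarray:
    """Copy-number vector over (locus, allele) slots for one individual.

    A homozygote contributes 2 to its allele's slot, a heterozygote 1 to
    each; missing loci contribute nothing.
    """
    i = table.index_of(individual)
    slots = allele_slots(table, loci_subset)
    vec = np.zeros(len(slots), dtype=int)
    for k, (locus, allele) in enumerate(slots):
        l = table.loci.index(locus)
        a, b = table.calls[i, l]
        if a == MISSING or b == MISSING:
            continue
        vec[k] = int(a == allele) + int(b == allele)
    return vec


def _abundance_array(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """All-individuals abundance array plus missing mask and per-locus slot offsets."""
    n, L = table.n, table.n_loci
    per_locus_alleles = []
    for l in range(L):
        alleles = np.unique(table.calls[:, l, :])
        per_locus_alleles.append([int(a) for a in alleles if a != MISSING])
    offsets = np.cumsum([0] + [len(a) for a in per_locus_alleles])
    abund = np.zeros((n, offsets[-1]), dtype=float)
    for l in range(L):
        index = {a: offsets[l] + k for k, a in enumerate(per_locus_alleles[l])}
        for i in range(n):
            a, b = table.calls[i, l]
            if a == MISSING or b == MISSING:
                continue
            abund[i, index[a]] += 1
            abund[i, index[b]] += 1
    return abund, table.missing_mask(), list(offsets)


def bray_curtis_matrix(table: GenotypeTable) -> GeneticDistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity of allele-abundance profiles.

    ``BC(i, j) = sum |a_i - a_j| / sum (a_i + a_j)`` over slots of loci that
    are non-missing in both individuals (pairwise deletion).  Raises if some
    pair shares no scorable locus.
    """
    if table.n < 2:
        raise ConfigurationError("need at least two individuals")
    abund, missing, offsets = _abundance_array(table)
    n, L = table.n, table.n_loci
    present = (~missing).astype(float)  # (n, L)
    shared = present @ present.T  # number of mutually non-missing loci
    bad = [(table.ids[i], table.ids[j]) for i, j in zip(*np.where(shared == 0)) if i < j]
    if bad:
        raise LandresError(f"pairs with no shared non-missing locus: {bad}")
    num = np.zeros((n, n))
    for l in range(L):
        block = abund[:, offsets[l]:offsets[l + 1]]
        # L1 distance between abundance rows at this locus, for every pair
        d = np.abs(block[:, None, :] - block[None, :, :]).sum(axis=2)
        ok = np.outer(present[:, l], present[:, l])
        num += d * ok
    denom = 4.0 * shared  # each scorable locus contributes 2 copies per individual
    values = num / denom
    np.fill_diagonal(values, 0.0)
    return GeneticDistanceMatrix(ids=list(table.ids), values=values, role="G")


def marker_summary(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus summary: allele count, Ho, unbiased He, missing fraction.

    He uses the small-sample correction ``(2n / (2n - 1)) (1 - sum p_k^2)``
    with n the number of scored individuals at the locus.
    """
    rows = []
    missing = table.missing_mask()
    for l, locus in enumerate(table.loci):
        scored = ~missing[:, l]
        n = int(scored.sum())
        calls = table.calls[scored, l, :]
        if n == 0:
            rows.append({"locus": locus, "n_alleles": 0, "Ho": np.nan,
                         "He": np.nan, "missing_fraction": 1.0})
            continue
        alleles, counts = np.unique(calls, return_counts=True)
        p = counts / counts.sum()
        ho = float((calls[:, 0] != calls[:, 1]).mean())
        he = 0.0
        if len(alleles) > 1:
            he = (2 * n / (2 * n - 1)) * (1 - float((p ** 2).sum()))
        rows.append({
            "locus": locus,
            "n_alleles": int(len(alleles)),
            "Ho": ho,
            "He": he,
            "missing_fraction": float(missing[:, l].mean()),
        })
    return pd.DataFrame(rows)
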