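"""Data model and text I/O for diploid microsatellite genotypes.

Allele calls are fragment lengths (positive integers) and are never recoded
to indices at this layer; numeric routines index internally.  Two community
text dialects are supported: Genepop (2- or 3-digit, auto-detected) and the
STRUCTURE one-row / two-row matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = 0  # sentinel allele code for a missing call

__all__ = [
    "Locus",
    "GenotypeDataset",
    "GenotypeParseError",
    "read_genepop",
    "write_genepop",
    "read_structure_table",
    "write_structure_table",
    "read_geography",
]


class GenotypeParseError(ValueError):
    """Raised when an input genotype file violates its dialect."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus, optionally placed on a linkage group (1-6)."""

    name: str
    linkage_group: int | None = None

    def __post_init__(self) -> None:
        if self.linkage_group is not None and not 1 <= self.linkage_group <= 6:
            raise ValueError(f"linkage_group must be in 1..6, got {self.linkage_group}")


@dataclass
class GenotypeDataset:
    """Individuals x loci diploid allele-length calls with population labels.

    Parameters
    ----------
    individuals
        Ordered individual ids (unique).
    loci
        Ordered :class:`Locus` records (unique names).
    calls
        int array of shape ``(n_individuals, n_loci, 2)``; allele labels are
        positive integers (fragment lengths), ``0`` in both slots = missing.
        Within a call the two alleles are an unordered pair; they are stored
        sorted ascending for a canonical form.
    site_labels, species_labels
        Per-individual sampling site and host/species (taxon) labels.
    pair_labels
        Optional site -> paired-site id; defaults to the site itself, i.e.
        populations of the two taxa sharing a site form a sympatric pair.
    """

    individuals: list[str]
    loci: list[Locus]
    calls: np.ndarray
    site_labels: list[str]
    species_labels: list[str]
    pair_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if len(self.site_labels) != n or len(self.species_labels) != n:
            raise ValueError("site/species labels must cover every individual")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing calls: a call has exactly two alleles or none")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be positive")
        self.calls = np.sort(self.calls, axis=2)

    # -- convenience ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def pair_of(self, site: str) -> str:
        return self.pair_labels.get(site, site)

    def population_labels(self, grouping: str = "site_species") -> list[str]:
        """Per-individual population label under a grouping scheme."""
        if grouping == "site":
            return list(self.site_labels)
        if grouping == "species":
            return list(self.species_labels)
        if grouping == "site_species":
            return [f"{s}_{sp}" for s, sp in zip(self.site_labels, self.species_labels)]
        raise ValueError(f"unknown grouping {grouping!r}")

    def subset(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = list(indices)
        return replace(
            self,
            individuals=[self.individuals[i] for i in idx],
            calls=self.calls[idx],
            site_labels=[self.site_labels[i] for i in idx],
            species_labels=[self.species_labels[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and self.site_labels == other.site_labels
            and self.species_labels == other.species_labels
        )


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _split_pop_label(label: str, sep: str = "_") -> tuple[str, str]:
    # population label "site_species"; species may not contain the separator
    if sep in label:
        site, species = label.rsplit(sep, 1)
        return site, species
    return label, "NA"


def read_genepop(path: str | Path, label_sep: str = "_") -> GenotypeDataset:
    """Read a Genepop file.

    The 2- vs 3-digit dialect is auto-detected from the genotype field width
    (4 or 6 characters); an ambiguous width is a hard error.  ``000000`` /
    ``0000`` encodes a missing call.  The name field before the comma is
    taken as the population label ``site<sep>species``; individual ids are
    autogenerated as ``label_<ordinal>``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError("empty file")
    it = iter(enumerate(lines[1:], start=2))  # skip title line

    locus_names: list[str] = []
    for lineno, raw in it:
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            break
        # locus names: one per line or comma-separated
        locus_names.extend(s.strip() for s in line.split(",") if s.strip())
    if len(set(locus_names)) != len(locus_names):
        raise GenotypeParseError("duplicate locus names")
    L = len(locus_names)

    pops: list[list[tuple[int, str, list[str]]]] = [[]]
    for lineno, raw in it:
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            pops.append([])
            continue
        if "," not in line:
            raise GenotypeParseError(f"line {lineno}: expected 'name , genotypes'")
        name, genos = line.split(",", 1)
        fields = genos.split()
        if len(fields) != L:
            raise GenotypeParseError(
                f"line {lineno}: {len(fields)} genotype fields, expected {L}"
            )
        pops[-1].append((lineno, name.strip(), fields))

    widths = {len(f) for block in pops for _, _, row in block for f in row}
    if not widths:
        # header-only file: no individuals
        return GenotypeDataset([], [Locus(nm) for nm in locus_names],
                               np.empty((0, L, 2), dtype=np.int64), [], [])
    if len(widths) != 1 or widths.pop() not in (4, 6):
        raise GenotypeParseError(
            "cannot auto-detect allele digit width: genotype fields must all "
            "be 4 (2-digit) or 6 (3-digit) characters"
        )
    digits = len(pops[0][0][2][0]) // 2 if pops[0] else 3
    for block in pops:
        if block:
            digits = len(block[0][2][0]) // 2
            break

    individuals, sites, species, rows = [], [], [], []
    for block in pops:
        if not block:
            continue
        label = block[0][1]
        site, sp = _split_pop_label(label, label_sep)
        for ordinal, (lineno, _name, fields) in enumerate(block, start=1):
            row = np.empty((L, 2), dtype=np.int64)
            for j, f in enumerate(fields):
                if not f.isdigit():
                    raise GenotypeParseError(f"line {lineno}: non-numeric genotype {f!r}")
                a1, a2 = int(f[:digits]), int(f[digits:])
                if (a1 == 0) != (a2 == 0):
                    raise GenotypeParseError(
                        f"line {lineno}: half-missing call {f!r}"
                    )
                row[j] = (a1, a2)
            individuals.append(f"{label}_{ordinal}")
            sites.append(site)
            species.append(sp)
            rows.append(row)

    calls = np.stack(rows) if rows else np.empty((0, L, 2), dtype=np.int64)
    return GenotypeDataset(individuals, [Locus(nm) for nm in locus_names],
                           calls, sites, species)


def write_genepop(dataset: GenotypeDataset, path: str | Path,
                  title: str = "hybridtrace export", label_sep: str = "_") -> None:
    """Write Genepop 3-digit format (missing call = ``000000``).

    Populations are ``site<sep>species`` groups in first-appearance order;
    the population label is written as the name field of every line.
    """
    if dataset.calls.size and dataset.calls.max() > 999:
        raise ValueError(
            "allele label > 999 cannot be encoded in 3-digit Genepop; "
            "use write_structure_table instead"
        )
    out = [title]
    out.extend(dataset.locus_names)
    pop_labels = dataset.population_labels("site_species")
    seen: dict[str, list[int]] = {}
    for i, lab in enumerate(pop_labels):
        seen.setdefault(lab, []).append(i)
    for lab, idx in seen.items():
        out.append("POP")
        for i in idx:
            genos = " ".join(
                f"{a1:03d}{a2:03d}" for a1, a2 in dataset.calls[i]
            )
            out.append(f"{lab} , {genos}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE
# ---------------------------------------------------------------------------

def read_structure_table(
    path: str | Path,
    rows_per_individual: int = 2,
    pop_labels: dict[int, str] | None = None,
    label_sep: str = "_",
) -> GenotypeDataset:
    """Read a STRUCTURE genotype matrix (no header row).

    Columns: individual id, integer population code, then one column per
    locus (two rows per individual) or two adjacent columns per locus (one
    row).  Missing is coded ``-9``.  Population codes become site labels
    via ``pop_labels`` when given, else ``pop<code>``; a mapped label of the
    form ``site<sep>species`` is split into the two fields.
    """
    if rows_per_individual not in (1, 2):
        raise ValueError("rows_per_individual must be 1 or 2")
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeParseError("empty file")
    ncol = len(lines[0])
    for k, row in enumerate(lines, start=1):
        if len(row) != ncol:
            raise GenotypeParseError(f"row {k}: ragged row ({len(row)} != {ncol} fields)")
    if rows_per_individual == 2 and len(lines) % 2:
        raise GenotypeParseError("odd row count in two-row mode")
    n_geno_cols = ncol - 2
    if rows_per_individual == 1 and n_geno_cols % 2:
        raise GenotypeParseError("one-row mode needs two allele columns per locus")
    L = n_geno_cols if rows_per_individual == 2 else n_geno_cols // 2

    def parse_int(tok: str, k: int) -> int:
        if not re.fullmatch(r"-?\d+", tok):
            raise GenotypeParseError(f"row {k}: non-integer allele field {tok!r}")
        return int(tok)

    individuals, sites, species, rows = [], [], [], []
    step = rows_per_individual
    for k in range(0, len(lines), step):
        block = lines[k:k + step]
        iid, code = block[0][0], block[0][1]
        if step == 2 and (block[1][0] != iid or block[1][1] != code):
            raise GenotypeParseError(
                f"rows {k + 1}-{k + 2}: the two rows of individual {iid!r} disagree"
            )
        label = (pop_labels or {}).get(int(code), f"pop{code}")
        site, sp = _split_pop_label(label, label_sep)
        row = np.empty((L, 2), dtype=np.int64)
        if step == 2:
            for j in range(L):
                a1 = parse_int(block[0][2 + j], k + 1)
                a2 = parse_int(block[1][2 + j], k + 2)
                row[j] = (a1, a2)
        else:
            for j in range(L):
                a1 = parse_int(block[0][2 + 2 * j], k + 1)
                a2 = parse_int(block[0][3 + 2 * j], k + 1)
                row[j] = (a1, a2)
        miss = row == -9
        if (miss.sum(axis=1) == 1).any():
            raise GenotypeParseError(f"individual {iid!r}: half-missing call")
        row[miss] = MISSING
        individuals.append(iid)
        sites.append(site)
        species.append(sp)
        rows.append(row)

    calls = np.stack(rows)
    loci = [Locus(f"L{j + 1}") for j in range(L)]
    return GenotypeDataset(individuals, loci, calls, sites, species)


def write_structure_table(
    dataset: GenotypeDataset, path: str | Path, rows_per_individual: int = 2
) -> dict[int, str]:
    """Write a STRUCTURE matrix; returns the pop-code -> label mapping used."""
    if rows_per_individual not in (1, 2):
        raise ValueError("rows_per_individual must be 1 or 2")
    labels = dataset.population_labels("site_species")
    codes: dict[str, int] = {}
    for lab in labels:
        codes.setdefault(lab, len(codes) + 1)
    out = []
    for i, iid in enumerate(dataset.individuals):
        code = codes[labels[i]]
        row = dataset.calls[i].copy()
        row[row == MISSING] = -9
        if rows_per_individual == 2:
            out.append(" ".join([iid, str(code)] + [str(a) for a in row[:, 0]]))
            out.append(" ".join([iid, str(code)] + [str(a) for a in row[:, 1]]))
        else:
            flat = row.reshape(-1)
            out.append(" ".join([iid, str(code)] + [str(a) for a in flat]))
    Path(path).write_text("\n".join(out) + "\n")
    return {v: k for k, v in codes.items()}


# ---------------------------------------------------------------------------
# Geography / covariate tables
# ---------------------------------------------------------------------------

def read_geography(path: str | Path) -> pd.DataFrame:
    """Read a site table: columns ``site, lat, lon[, pair, species,
    precip_jul_oct, tmax_jul, tmin_jan]`` (comma- or tab-delimited, header
    required).  Missing ``pair`` defaults to the site itself."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"site", "lat", "lon"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(
            f"geography table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    df["site"] = df["site"].astype(str)
    if "pair" not in df.columns:
        df["pair"] = df["site"]
    if df["site"].duplicated().any():
        raise GenotypeParseError("duplicate site rows in geography table")
    return df.set_index("site", drop=False)
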