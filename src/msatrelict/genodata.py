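"""Domain types and file I/O for mixed-ploidy microsatellite genotype data.

A dataset is a collection of individuals genotyped at a shared, ordered panel
of microsatellite loci.  Each genotype is the *observed* multiset of allele
sizes (fragment lengths in base pairs).  Diploids carry up to two alleles;
autotetraploids carry up to four, with ambiguous dosage when fewer than four
distinct sizes are observed (an electropherogram shows which alleles are
present, not how many copies of each).  An empty multiset encodes missing
data.

Three text formats are supported:

* a CSV dialect with four allele columns per locus (the only dialect that can
  carry tetraploid genotypes),
* the GenePop dialect (diploid interchange only), and
* a Structure input file using the recessive-alleles coding for mixed
  2x/4x data (export only).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Locus",
    "Genotype",
    "Individual",
    "Population",
    "MsatDataset",
    "MISSING",
    "read_csv_dataset",
    "write_csv_dataset",
    "read_genepop",
    "export_structure_recessive",
]

#: canonical missing genotype (empty allele multiset)
MISSING: tuple[int, ...] = ()


class DataFormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker.

    Parameters
    ----------
    name:
        Short identifier, unique within a dataset.
    motif_length:
        Repeat-unit length in base pairs (>= 1).  Used to convert fragment
        sizes to repeat counts inside size-based statistics.
    """

    name: str
    motif_length: int = 2

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")
        if not self.name:
            raise ValueError("locus name must be non-empty")


@dataclass(frozen=True)
class Genotype:
    """Observed multiset of 0-4 allele sizes (bp) at one locus.

    The multiset is stored sorted; an empty tuple means missing data.
    """

    allele_sizes: tuple[int, ...]

    def __init__(self, allele_sizes: Iterable[int] = ()) -> None:
        sizes = tuple(sorted(int(a) for a in allele_sizes))
        if len(sizes) > 4:
            raise ValueError(f"at most 4 alleles per genotype, got {len(sizes)}")
        if any(a <= 0 for a in sizes):
            raise ValueError(f"allele sizes must be positive integers: {sizes}")
        object.__setattr__(self, "allele_sizes", sizes)

    @property
    def is_missing(self) -> bool:
        return not self.allele_sizes

    @property
    def distinct(self) -> tuple[int, ...]:
        return tuple(dict.fromkeys(self.allele_sizes))

    @property
    def observed_distinct(self) -> int:
        return len(set(self.allele_sizes))

    def __len__(self) -> int:
        return len(self.allele_sizes)


@dataclass
class Population:
    """Sampling-site record."""

    code: str
    country: str = ""
    altitude: float | None = None


@dataclass
class Individual:
    """One genotyped individual.

    ``ploidy`` may be ``None`` before ploidy inference has run.  When set, no
    genotype may show more distinct alleles than the ploidy level.
    """

    id: str
    population: str
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    ploidy: int | None = None

    def validate(self, loci: Sequence[Locus]) -> None:
        names = {l.name for l in loci}
        for locus_name, g in self.genotypes.items():
            if locus_name not in names:
                raise ValueError(f"{self.id}: unknown locus {locus_name!r}")
            if self.ploidy is not None and g.observed_distinct > self.ploidy:
                raise ValueError(
                    f"{self.id}: {g.observed_distinct} distinct alleles at "
                    f"{locus_name} exceeds ploidy {self.ploidy}"
                )

    def max_distinct(self) -> int:
        """Largest number of distinct alleles seen at any single locus."""
        return max((g.observed_distinct for g in self.genotypes.values()), default=0)

    def missing_fraction(self, loci: Sequence[Locus]) -> float:
        n = len(loci)
        miss = sum(1 for l in loci if self.genotypes.get(l.name, Genotype()).is_missing)
        return miss / n if n else 0.0


@dataclass
class MsatDataset:
    """Populations x individuals x loci table of allele-size multisets."""

    loci: list[Locus]
    populations: dict[str, Population]
    individuals: list[Individual]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        for ind in self.individuals:
            if ind.population not in self.populations:
                raise ValueError(
                    f"individual {ind.id} references unknown population "
                    f"{ind.population!r}"
                )
            ind.validate(self.loci)

    # -- basic queries ---------------------------------------------------

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def population_individuals(self, code: str) -> list[Individual]:
        if code not in self.populations:
            raise KeyError(f"unknown population {code!r}")
        return [i for i in self.individuals if i.population == code]

    def missing_fraction(self) -> float:
        """Fraction of (individual, locus) cells with no genotype."""
        n_cells = len(self.individuals) * len(self.loci)
        if n_cells == 0:
            return 0.0
        miss = sum(
            1
            for ind in self.individuals
            for l in self.loci
            if ind.genotypes.get(l.name, Genotype()).is_missing
        )
        return miss / n_cells

    def summary(self) -> dict:
        return {
            "n_individuals": len(self.individuals),
            "n_populations": len(self.populations),
            "n_loci": len(self.loci),
            "missing_fraction": self.missing_fraction(),
        }


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
#
# Column schema (header row required):
#   individual, population, country, altitude, ploidy, then for each locus L
#   four columns "L.1" .. "L.4".  Unused allele slots and missing genotypes
#   are blank or the sentinel (default -9).  ploidy may be blank (= unset).

_META_COLS = ["individual", "population", "country", "altitude", "ploidy"]


def _parse_allele(token: str, sentinel: int) -> int | None:
    token = token.strip()
    if not token:
        return None
    value = int(token)
    if value == sentinel:
        return None
    return value


def read_csv_dataset(
    path,
    motif_lengths: Mapping[str, int] | None = None,
    missing_sentinel: int = -9,
) -> MsatDataset:
    """Read the 4-alleles-per-locus CSV dialect.

    Parameters
    ----------
    path:
        File path or open text handle.
    motif_lengths:
        Optional mapping locus name -> repeat motif length (bp); defaults
        to 2 (dinucleotide) for unlisted loci.
    missing_sentinel:
        Integer that, like a blank cell, marks an absent allele entry.
    """
    close = False
    if hasattr(path, "read"):
        handle = path
    else:
        handle = open(path, "r", newline="")
        close = True
    try:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise DataFormatError("empty CSV file") from None
        header = [h.strip() for h in header]
        if header[: len(_META_COLS)] != _META_COLS:
            raise DataFormatError(
                f"CSV header must start with {_META_COLS}, got {header[:5]}"
            )
        allele_cols = header[len(_META_COLS) :]
        if len(allele_cols) % 4 != 0:
            raise DataFormatError("expected 4 allele columns per locus")
        locus_names: list[str] = []
        for i in range(0, len(allele_cols), 4):
            block = allele_cols[i : i + 4]
            base = block[0].rsplit(".", 1)[0]
            if block != [f"{base}.{k}" for k in (1, 2, 3, 4)]:
                raise DataFormatError(f"malformed allele column block {block}")
            locus_names.append(base)
        motif_lengths = dict(motif_lengths or {})
        loci = [Locus(n, motif_lengths.get(n, 2)) for n in locus_names]

        populations: dict[str, Population] = {}
        individuals: list[Individual] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise DataFormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            ind_id, pop_code, country, altitude, ploidy = (c.strip() for c in row[:5])
            if pop_code not in populations:
                populations[pop_code] = Population(
                    code=pop_code,
                    country=country,
                    altitude=float(altitude) if altitude else None,
                )
            genotypes: dict[str, Genotype] = {}
            for j, name in enumerate(locus_names):
                cells = row[5 + 4 * j : 9 + 4 * j]
                try:
                    alleles = [
                        a
                        for c in cells
                        if (a := _parse_allele(c, missing_sentinel)) is not None
                    ]
                    genotypes[name] = Genotype(alleles)
                except ValueError as exc:
                    raise DataFormatError(f"line {lineno}, locus {name}: {exc}") from exc
            individuals.append(
                Individual(
                    id=ind_id,
                    population=pop_code,
                    genotypes=genotypes,
                    ploidy=int(ploidy) if ploidy else None,
                )
            )
    finally:
        if close:
            handle.close()
    return MsatDataset(loci=loci, populations=populations, individuals=individuals)


def write_csv_dataset(dataset: MsatDataset, path, missing_sentinel: int = -9) -> None:
    """Write the CSV dialect (inverse of :func:`read_csv_dataset`)."""
    close = False
    if hasattr(path, "write"):
        handle = path
    else:
        handle = open(path, "w", newline="")
        close = True
    try:
        writer = csv.writer(handle, lineterminator="\n")
        header = list(_META_COLS)
        for l in dataset.loci:
            header.extend(f"{l.name}.{k}" for k in (1, 2, 3, 4))
        writer.writerow(header)
        for ind in dataset.individuals:
            pop = dataset.populations[ind.population]
            row = [
                ind.id,
                pop.code,
                pop.country,
                "" if pop.altitude is None else f"{pop.altitude:g}",
                "" if ind.ploidy is None else str(ind.ploidy),
            ]
            for l in dataset.loci:
                alleles = list(ind.genotypes.get(l.name, Genotype()).allele_sizes)
                row.extend(str(a) for a in alleles)
                row.extend("" for _ in range(4 - len(alleles)))
            writer.writerow(row)
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# GenePop dialect (diploid interchange only)
# ---------------------------------------------------------------------------


def read_genepop(
    path,
    allele_offsets: Mapping[str, int] | None = None,
    motif_lengths: Mapping[str, int] | None = None,
) -> MsatDataset:
    """Read a GenePop file (3-digit allele coding, ``POP``-delimited).

    GenePop carries exactly two alleles per genotype, so this dialect is
    diploid-only; tetraploid data must use the CSV dialect.  Allele codes
    are converted to fragment sizes as ``size = offset + code`` with a
    per-locus offset table (default offset 0, i.e. codes are sizes).
    ``000000`` (or ``0000``) encodes a missing genotype.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln.rstrip("\n") for ln in io.StringIO(text)]
    if not lines:
        raise DataFormatError("empty GenePop file")
    # line 1 is a free-text title
    body = lines[1:]
    locus_names: list[str] = []
    idx = 0
    while idx < len(body) and body[idx].strip().upper() != "POP":
        chunk = body[idx].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        idx += 1
    if not locus_names:
        raise DataFormatError("no locus names before first POP")
    offsets = dict(allele_offsets or {})
    motif_lengths = dict(motif_lengths or {})
    loci = [Locus(n, motif_lengths.get(n, 2)) for n in locus_names]

    populations: dict[str, Population] = {}
    individuals: list[Individual] = []
    pop_counter = 0
    current_pop: str | None = None
    for lineno, line in enumerate(body[idx:], start=idx + 2):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.upper() == "POP":
            pop_counter += 1
            current_pop = f"POP{pop_counter}"
            populations[current_pop] = Population(code=current_pop)
            continue
        if current_pop is None:
            raise DataFormatError(f"line {lineno}: genotype row before first POP")
        if "," not in stripped:
            raise DataFormatError(f"line {lineno}: expected 'name , genotypes'")
        name_part, geno_part = stripped.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise DataFormatError(
                f"line {lineno}: expected {len(loci)} genotypes, got {len(tokens)}"
            )
        genotypes: dict[str, Genotype] = {}
        for locus, tok in zip(loci, tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise DataFormatError(
                    f"line {lineno}, locus {locus.name}: bad genotype token {tok!r}"
                )
            w = len(tok) // 2
            codes = [int(tok[:w]), int(tok[w:])]
            off = offsets.get(locus.name, 0)
            alleles = [off + c for c in codes if c != 0]
            genotypes[locus.name] = Genotype(alleles)
        individuals.append(
            Individual(
                id=name_part.strip(),
                population=current_pop,
                genotypes=genotypes,
                ploidy=2,
            )
        )
    return MsatDataset(loci=loci, populations=populations, individuals=individuals)


# ---------------------------------------------------------------------------
# Structure export with the recessive-alleles coding
# ---------------------------------------------------------------------------

STRUCTURE_MISSING = -5  # also used as the recessive-allele code
STRUCTURE_NOTAMBIGUOUS = -1


def _pad_to_four(distinct: Sequence[int]) -> list[int]:
    """Pad an ambiguous tetraploid allele set to four named entries.

    Three observed alleles A,B,C become A,B,C,C (the last observed allele
    replicated).  Two observed alleles are padded *balanced* to A,A,B,B;
    one observed allele to A,A,A,A.  The balanced rule for the 2-allele case
    is this package's deterministic convention (any replication of observed
    alleles is genotype-compatible).
    """
    k = len(distinct)
    if k == 4:
        return list(distinct)
    if k == 3:
        return [distinct[0], distinct[1], distinct[2], distinct[2]]
    if k == 2:
        return [distinct[0], distinct[0], distinct[1], distinct[1]]
    if k == 1:
        return [distinct[0]] * 4
    raise ValueError("empty genotype cannot be padded")


def export_structure_recessive(dataset: MsatDataset, path) -> None:
    """Write a Structure input file for mixed diploid/tetraploid data.

    Layout: one row per individual with four allele entries per locus.
    Tetraploid ambiguous genotypes are padded to four entries by replicating
    observed alleles (see :func:`_pad_to_four`); diploid genotypes are
    written as their two alleles followed by two missing codes, which under
    the recessive-alleles model marks them as diploid.  The header comment
    block records the parameter conventions: missing and recessive-allele
    code -5, "notambiguous" code -1, ploidy 4.

    Output is byte-stable for a fixed dataset ordering.
    """
    for ind in dataset.individuals:
        if ind.ploidy is None:
            raise ValueError(f"individual {ind.id} has unset ploidy; run ploidy "
                             "inference before Structure export")
        for name, g in ind.genotypes.items():
            if any(a in (STRUCTURE_MISSING, STRUCTURE_NOTAMBIGUOUS)
                   for a in g.allele_sizes):
                raise ValueError(
                    f"{ind.id}/{name}: allele equal to a sentinel code"
                )

    pop_index = {code: i + 1 for i, code in enumerate(dataset.populations)}
    close = False
    if hasattr(path, "write"):
        handle = path
    else:
        handle = open(path, "w", newline="")
        close = True
    try:
        w = handle.write
        w("# Structure input, recessive-alleles coding for mixed 2x/4x data\n")
        w(f"# MISSING={STRUCTURE_MISSING} RECESSIVEALLELE={STRUCTURE_MISSING} "
          f"NOTAMBIGUOUS={STRUCTURE_NOTAMBIGUOUS} PLOIDY=4\n")
        w("# tetraploid padding: 3 observed -> A B C C; 2 observed -> A A B B; "
          "1 observed -> A A A A\n")
        w("# columns: individual population " +
          " ".join(f"{l.name}.{k}" for l in dataset.loci for k in (1, 2, 3, 4)) +
          "\n")
        for ind in dataset.individuals:
            entries: list[int] = []
            for l in dataset.loci:
                g = ind.genotypes.get(l.name, Genotype())
                if g.is_missing:
                    entries.extend([STRUCTURE_MISSING] * 4)
                elif ind.ploidy == 2:
                    a = list(g.distinct)
                    pair = [a[0], a[0]] if len(a) == 1 else [a[0], a[1]]
                    entries.extend(pair + [STRUCTURE_MISSING, STRUCTURE_MISSING])
                else:
                    entries.extend(_pad_to_four(g.distinct))
            w(f"{ind.id} {pop_index[ind.population]} "
              + " ".join(str(e) for e in entries) + "\n")
    finally:
        if close:
            handle.close()
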