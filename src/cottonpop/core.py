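"""Core domain types shared across the pipeline.

Coordinate convention: every interval held in memory is 0-based, half-open
``[start, end)``.  VCF, GFF3 and 1-based TSV inputs are converted at the I/O
boundary and converted back on output.

Genotypes are diploid-coded alternate-allele dosages in ``{0, 1, 2}`` with
``-1`` marking a missing call.  Tetraploidy is represented structurally: the A
and D subgenomes are separate chromosomes in the layout, reflecting reads
assigned uniquely to one subgenome before genotyping, so each site behaves as
a diploid biallelic locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SPECIES = ("hirsutum", "barbadense", "outgroup")
GROUPS = ("race", "cultivar", "landrace", "outgroup")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    subgenome: str  # "A" or "D" ("O" allowed for outgroup scaffolds)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.subgenome not in ("A", "D", "O"):
            raise ValueError(f"chromosome {self.name}: bad subgenome tag "
                             f"{self.subgenome!r}")


@dataclass(frozen=True)
class HomoeologLink:
    """A coordinate correspondence between an A-subgenome interval and its
    homoeologous D-subgenome interval (both 0-based half-open)."""
    a_chrom: str
    a_start: int
    a_end: int
    d_chrom: str
    d_start: int
    d_end: int


@dataclass
class GenomeLayout:
    chromosomes: list[Chromosome]
    homoeolog_map: list[HomoeologLink] = field(default_factory=list)

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        lengths = self.lengths()
        for link in self.homoeolog_map:
            for chrom, s, e in ((link.a_chrom, link.a_start, link.a_end),
                                (link.d_chrom, link.d_start, link.d_end)):
                if chrom not in lengths:
                    raise ValueError(f"homoeolog interval on unknown "
                                     f"chromosome {chrom}")
                if not (0 <= s < e <= lengths[chrom]):
                    raise ValueError(f"homoeolog interval {chrom}:{s}-{e} "
                                     f"outside chromosome")

    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def subgenome_of(self, chrom: str) -> str:
        for c in self.chromosomes:
            if c.name == chrom:
                return c.subgenome
        raise KeyError(chrom)

    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


class AccessionPanel:
    """Accession metadata: id, species, group, origin.

    Wraps a DataFrame; ids are unique and order is meaningful (it fixes the
    row order of every GenotypeMatrix built against the panel).
    """

    COLUMNS = ("id", "species", "group", "origin")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        for col in self.COLUMNS:
            if col not in table.columns:
                if col == "origin":
                    table["origin"] = ""
                else:
                    raise ValueError(f"panel missing column {col!r}")
        if table["id"].duplicated().any():
            dups = table.loc[table["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate accession ids: {dups}")
        bad = set(table["species"]) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species labels: {sorted(bad)}")
        bad = set(table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.table = table.reset_index(drop=True)[list(self.COLUMNS)]

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, AccessionPanel) and self.table.equals(other.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def index_of(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.table["id"])}
        try:
            return np.array([pos[a] for a in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"accession {e.args[0]!r} not in panel") from None

    def ids_where(self, species=None, group=None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if species is not None:
            mask &= self.table["species"] == species
        if group is not None:
            mask &= self.table["group"] == group
        return self.table.loc[mask, "id"].tolist()

    def subset(self, ids) -> "AccessionPanel":
        idx = self.index_of(ids)
        return AccessionPanel(self.table.iloc[idx])


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based, as printed in VCF
    ref: str
    alt: str
    vtype: str  # "snp" | "indel"

    @property
    def indel_length(self) -> int:
        return len(self.alt) - len(self.ref)

    def __post_init__(self):
        if self.vtype == "snp" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError(f"SNP at {self.chrom}:{self.pos} must have "
                             f"single-base alleles")


#: dtype of the per-matrix site table
SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "vtype")


class GenotypeMatrix:
    """Accessions x biallelic sites with dosages in {0,1,2,-1(missing)}.

    ``sites`` is a DataFrame with columns chrom, pos (1-based), ref, alt,
    vtype, sorted by (chrom, pos) within the chromosome order implied by the
    data.  ``calls`` has shape (n_accessions, n_sites), dtype int8.
    """

    def __init__(self, panel: AccessionPanel, sites: pd.DataFrame,
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(panel), len(sites)):
            raise ValueError(f"calls shape {calls.shape} inconsistent with "
                             f"{len(panel)} accessions x {len(sites)} sites")
        if calls.size and not ((calls >= -1) & (calls <= 2)).all():
            raise ValueError("calls must be in {-1,0,1,2}")
        sites = sites.reset_index(drop=True)
        for chrom, sub in sites.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"sites not sorted by position on {chrom}")
        self.panel = panel
        self.sites = sites
        self.calls = calls

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.panel)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.panel == other.panel
                and self.sites.equals(other.sites)
                and np.array_equal(self.calls, other.calls))

    def site(self, i: int) -> VariantSite:
        row = self.sites.iloc[i]
        return VariantSite(row["chrom"], int(row["pos"]), row["ref"],
                           row["alt"], row["vtype"])

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(self.panel, self.sites.iloc[index],
                              self.calls[:, index])

    def rows(self, ids) -> np.ndarray:
        """Call rows for the given accession ids (view into calls)."""
        return self.calls[self.panel.index_of(ids), :]

    def alt_frequency(self, ids=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site alt-allele frequency and called-allele count.

        Frequency is alt-allele count / called-allele count (missing calls
        excluded from the denominator); NaN where nothing is called.
        """
        sub = self.calls if ids is None else self.rows(ids)
        called = sub >= 0
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1),
                            np.nan)
        return freq, n_alleles

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.panel, self.sites.copy(),
                              self.calls.copy())


@dataclass
class GeneModel:
    """A protein-coding gene model: CDS segments in transcript (5'->3') order.

    Segments are 1-based closed intervals on the chromosome, as in GFF3;
    ``phase`` is the phase of the first segment.  ``frame_warning`` is set
    when the phase-adjusted CDS length is not a multiple of 3.
    """
    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    cds: list[tuple[int, int]]
    phase: int = 0
    frame_warning: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        ordered = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        self.frame_warning = (self.cds_length() - self.phase) % 3 != 0

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def genomic_positions(self) -> np.ndarray:
        """1-based genomic positions of CDS bases in transcript order."""
        segs = sorted(self.cds)
        pos = np.concatenate([np.arange(s, e + 1) for s, e in segs])
        return pos[::-1] if self.strand == "-" else pos

    def span(self) -> tuple[int, int]:
        """0-based half-open genomic span of the CDS."""
        segs = sorted(self.cds)
        return segs[0][0] - 1, segs[-1][1]


class IntervalSet:
    """Named genomic intervals (0-based half-open).  Overlaps allowed."""

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=["chrom", "start", "end", "label"])
        df = df.copy().reset_index(drop=True)
        if "label" not in df.columns:
            df["label"] = [f"iv{i}" for i in range(len(df))]
        bad = df["start"] >= df["end"]
        if bad.any():
            raise ValueError(f"empty/negative intervals at rows "
                             f"{list(df.index[bad])}")
        self.df = df[["chrom", "start", "end", "label"]]

    @classmethod
    def from_tuples(cls, tuples) -> "IntervalSet":
        rows = []
        for t in tuples:
            chrom, start, end = t[:3]
            label = t[3] if len(t) > 3 else f"iv{len(rows)}"
            rows.append((chrom, int(start), int(end), label))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                               "label"]))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield row.chrom, int(row.start), int(row.end), row.label

    def on(self, chrom: str) -> "IntervalSet":
        return IntervalSet(self.df[self.df["chrom"] == chrom])


def make_windows(layout: GenomeLayout, size: int = 100_000) -> IntervalSet:
    """Non-overlapping windows tiling every chromosome (last window clipped)."""
    rows = []
    for c in layout.chromosomes:
        for start in range(0, c.length, size):
            end = min(start + size, c.length)
            rows.append((c.name, start, end,
                         f"{c.name}:{start}-{end}"))
    return IntervalSet.from_tuples(rows)


def default_layout(chrom_length: int = 2_000_000) -> GenomeLayout:
    """Desk-scale allotetraploid layout: A01, A02, D01, D02, with full-length
    homoeologous correspondence A01<->D01 and A02<->D02."""
    chroms = [Chromosome("A01", chrom_length, "A"),
              Chromosome("A02", chrom_length, "A"),
              Chromosome("D01", chrom_length, "D"),
              Chromosome("D02", chrom_length, "D")]
    links = [HomoeologLink("A01", 0, chrom_length, "D01", 0, chrom_length),
             HomoeologLink("A02", 0, chrom_length, "D02", 0, chrom_length)]
    return GenomeLayout(chroms, links)
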