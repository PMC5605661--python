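"""Gene domain architecture, protein-level mutation records and domain tallies.

The unit of analysis is a protein-level variant placed on a linear domain map
of a single gene product (here, the Trio-9 isoform: Sec14, nine spectrin
repeats, the tandem GEF cassettes DH1-PH1 and DH2-PH2, and SH3).  Variants
from affected individuals (de novo), their unaffected parents (inherited) and
unaffected controls are tallied per domain, and a per-domain enrichment score
is the excess of case de novo events over control events.

Coordinates are 1-based inclusive residue positions in protein space; there
is no nucleotide-coordinate logic here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DomainInterval",
    "GeneModel",
    "MutationRecord",
    "DomainTally",
    "INTER_DOMAIN",
    "MUTATION_CLASSES",
    "COHORTS",
    "assign_domain",
    "assign_record_domain",
    "tally_mutations",
    "enrichment_score",
    "read_gene_model",
    "read_mutations",
    "write_tally",
]

#: Sentinel column for variants falling outside every annotated domain.
INTER_DOMAIN = "inter-domain"

MUTATION_CLASSES = frozenset({"missense", "lof", "synonymous"})
COHORTS = frozenset({"case_de_novo", "control", "inherited"})

#: Tally rows in presentation order; total rows are derived, never stored.
BASE_ROWS = (
    "case_dn_missense",
    "case_dn_lof",
    "inherited_missense",
    "inherited_lof",
    "control_missense",
    "control_lof",
)
TOTAL_CASE = "total_case"
TOTAL_CONTROL = "total_control"


@dataclass(frozen=True, order=True)
class DomainInterval:
    """A named domain segment, 1-based inclusive on the protein sequence."""

    start_aa: int
    end_aa: int
    name: str = field(compare=False)

    def __init__(self, name: str, start_aa: int, end_aa: int):
        if start_aa < 1 or end_aa < start_aa:
            raise ValueError(
                f"invalid domain interval {name!r}: [{start_aa}, {end_aa}]"
            )
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "start_aa", int(start_aa))
        object.__setattr__(self, "end_aa", int(end_aa))

    @property
    def length_aa(self) -> int:
        return self.end_aa - self.start_aa + 1

    def __contains__(self, position: int) -> bool:
        return self.start_aa <= position <= self.end_aa


@dataclass(frozen=True)
class GeneModel:
    """A protein's length and ordered, non-overlapping domain segmentation."""

    gene_symbol: str
    protein_length_aa: int
    domains: tuple[DomainInterval, ...]
    reference_accession: str = ""

    def __post_init__(self):
        if self.protein_length_aa < 1:
            raise ValueError("protein_length_aa must be positive")
        object.__setattr__(self, "domains", tuple(self.domains))
        prev_end = 0
        for dom in self.domains:
            if dom.start_aa <= prev_end:
                raise ValueError(
                    f"domains must be ascending and non-overlapping; "
                    f"{dom.name!r} starts at {dom.start_aa} after position {prev_end}"
                )
            if dom.end_aa > self.protein_length_aa:
                raise ValueError(
                    f"domain {dom.name!r} extends past protein end "
                    f"({dom.end_aa} > {self.protein_length_aa})"
                )
            prev_end = dom.end_aa
        names = [d.name for d in self.domains]
        if len(set(names)) != len(names):
            raise ValueError("domain names must be unique")

    @property
    def domain_names(self) -> list[str]:
        return [d.name for d in self.domains]

    def domain(self, name: str) -> DomainInterval:
        for dom in self.domains:
            if dom.name == name:
                return dom
        raise KeyError(f"no domain named {name!r} in {self.gene_symbol}")


@dataclass(frozen=True)
class MutationRecord:
    """One protein-level variant.

    ``protein_position_aa`` is the (first) affected residue; truncations and
    CNV deletions additionally carry ``end_position_aa`` for the end of the
    affected range.  ``mclass`` 'lof' covers nonsense, frameshift and CNV
    deletion events.
    """

    protein_position_aa: int
    mclass: str
    cohort: str
    gene: str = ""
    end_position_aa: int | None = None
    ref_aa: str = ""
    alt_description: str = ""
    dna_change: str = ""
    diagnosis: str | None = None

    def __post_init__(self):
        if self.mclass not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mclass!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.protein_position_aa < 1:
            raise ValueError("protein_position_aa must be >= 1")
        if (
            self.end_position_aa is not None
            and self.end_position_aa < self.protein_position_aa
        ):
            raise ValueError("end_position_aa precedes protein_position_aa")

    def validate_against(self, gene: GeneModel) -> None:
        end = self.end_position_aa or self.protein_position_aa
        if end > gene.protein_length_aa:
            raise ValueError(
                f"record at {self.protein_position_aa}"
                f"{'-' + str(self.end_position_aa) if self.end_position_aa else ''} "
                f"outside {gene.gene_symbol} (length {gene.protein_length_aa})"
            )


def assign_domain(position: int, gene: GeneModel) -> str:
    """Name of the domain containing ``position``, else ``'inter-domain'``."""
    if not 1 <= position <= gene.protein_length_aa:
        raise ValueError(
            f"position {position} outside [1, {gene.protein_length_aa}]"
        )
    for dom in gene.domains:
        if position in dom:
            return dom.name
    return INTER_DOMAIN


def assign_record_domain(
    record: MutationRecord, gene: GeneModel, multi_domain: bool = False
) -> str | list[str]:
    """Domain attribution for a record, including ranged (CNV/truncation) ones.

    Point records get the domain of their residue.  Ranged records are
    attributed to the domain of their first affected residue if that residue
    is annotated, otherwise to the first annotated domain overlapped by the
    range, so that a deletion sweeping several domains is counted once.  With
    ``multi_domain=True`` a ranged record instead returns every overlapped
    domain.
    """
    record.validate_against(gene)
    start = record.protein_position_aa
    end = record.end_position_aa
    if end is None:
        return assign_domain(start, gene)
    hits = [
        d.name
        for d in gene.domains
        if d.start_aa <= end and d.end_aa >= start
    ]
    if multi_domain:
        return hits or [INTER_DOMAIN]
    first = assign_domain(start, gene)
    if first != INTER_DOMAIN:
        return first
    return hits[0] if hits else INTER_DOMAIN


class DomainTally:
    """Count matrix of mutation classes x domains, with derived total rows.

    Only the six base rows are stored; ``total_case`` and ``total_control``
    are always computed from them, so the bookkeeping identities
    ``total_case = case_dn_missense + case_dn_lof`` and
    ``total_control = inherited + control`` hold by construction.
    """

    def __init__(self, counts: pd.DataFrame):
        missing = [r for r in BASE_ROWS if r not in counts.index]
        if missing:
            raise ValueError(f"tally missing rows: {missing}")
        counts = counts.loc[list(BASE_ROWS)].astype(int)
        if (counts.values < 0).any():
            raise ValueError("tally counts must be non-negative")
        self._counts = counts

    @classmethod
    def zeros(cls, domain_names: Sequence[str]) -> "DomainTally":
        cols = list(domain_names) + [INTER_DOMAIN]
        return cls(pd.DataFrame(0, index=list(BASE_ROWS), columns=cols))

    @property
    def columns(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def base_counts(self) -> pd.DataFrame:
        return self._counts.copy()

    @property
    def total_case(self) -> pd.Series:
        return (
            self._counts.loc["case_dn_missense"] + self._counts.loc["case_dn_lof"]
        ).rename(TOTAL_CASE)

    @property
    def total_control(self) -> pd.Series:
        return (
            self._counts.loc["inherited_missense"]
            + self._counts.loc["inherited_lof"]
            + self._counts.loc["control_missense"]
            + self._counts.loc["control_lof"]
        ).rename(TOTAL_CONTROL)

    def to_frame(self) -> pd.DataFrame:
        """Full matrix including the derived total rows."""
        return pd.concat(
            [self._counts, self.total_case.to_frame().T, self.total_control.to_frame().T]
        )

    def __getitem__(self, row: str) -> pd.Series:
        if row == TOTAL_CASE:
            return self.total_case
        if row == TOTAL_CONTROL:
            return self.total_control
        return self._counts.loc[row]

    def __eq__(self, other) -> bool:
        return isinstance(other, DomainTally) and self._counts.equals(other._counts)

    def __add__(self, other: "DomainTally") -> "DomainTally":
        if self.columns != other.columns:
            raise ValueError("tallies have different domain columns")
        return DomainTally(self._counts + other._counts)

    def grand_total(self, row: str) -> int:
        return int(self[row].sum())


def _tally_row(record: MutationRecord) -> str:
    cohort_key = {"case_de_novo": "case_dn", "inherited": "inherited", "control": "control"}
    cls = record.mclass
    if cls == "synonymous":
        raise ValueError("synonymous records are not tallied; filter them first")
    return f"{cohort_key[record.cohort]}_{cls}"


def tally_mutations(
    mutations: Iterable[MutationRecord],
    gene: GeneModel,
    multi_domain_cnv: bool = False,
) -> DomainTally:
    """Count every protein-altering record exactly once into its
    (row, domain) cell; synonymous records are skipped (the burden analysis
    concerns protein-altering events only)."""
    tally = DomainTally.zeros(gene.domain_names)
    counts = tally._counts
    for rec in mutations:
        if rec.mclass == "synonymous":
            continue
        row = _tally_row(rec)
        domains = assign_record_domain(rec, gene, multi_domain=multi_domain_cnv)
        if isinstance(domains, str):
            domains = [domains]
        for dom in domains:
            counts.loc[row, dom] += 1
    return tally


def enrichment_score(tally: DomainTally) -> pd.Series:
    """Per-domain signed excess: case de novo events minus control events."""
    return (tally.total_case - tally.total_control).rename("enrichment")


# ---------------------------------------------------------------------------
# IO: TSV/JSON annotation, mutation lists, tally output


def read_gene_model(path: str | Path) -> GeneModel:
    """Read a gene/domain annotation from TSV (name/start/end + header
    comments carrying gene metadata) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return GeneModel(
            gene_symbol=payload["gene_symbol"],
            protein_length_aa=int(payload["protein_length_aa"]),
            reference_accession=payload.get("reference_accession", ""),
            domains=tuple(
                DomainInterval(d["name"], int(d["start"]), int(d["end"]))
                for d in payload["domains"]
            ),
        )
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#") and "=" in line:
            key, _, value = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = value.strip()
    table = pd.read_csv(path, sep="\t", comment="#")
    domains = tuple(
        DomainInterval(row["name"], int(row["start"]), int(row["end"]))
        for _, row in table.iterrows()
    )
    return GeneModel(
        gene_symbol=meta.get("gene_symbol", path.stem),
        protein_length_aa=int(meta.get("protein_length_aa", domains[-1].end_aa)),
        reference_accession=meta.get("reference_accession", ""),
        domains=domains,
    )


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a mutation list TSV (gene, position, end_position, ref_aa, alt,
    dna_change, mclass, cohort, diagnosis; '#' comments allowed)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene", "position", "mclass", "cohort"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        end = row.get("end_position")
        end_val = None if pd.isna(end) or end in ("", ".") else int(float(end))
        records.append(
            MutationRecord(
                gene=row["gene"],
                protein_position_aa=int(float(row["position"])),
                end_position_aa=end_val,
                ref_aa="" if pd.isna(row.get("ref_aa")) else str(row.get("ref_aa")),
                alt_description="" if pd.isna(row.get("alt")) else str(row.get("alt")),
                dna_change="" if pd.isna(row.get("dna_change")) else str(row.get("dna_change")),
                mclass=row["mclass"],
                cohort=row["cohort"],
                diagnosis=None if pd.isna(row.get("diagnosis")) else str(row.get("diagnosis")),
            )
        )
    return records


def write_tally(tally: DomainTally, path: str | Path) -> None:
    tally.to_frame().to_csv(path, sep="\t", index_label="row")


def read_tally(path: str | Path) -> DomainTally:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return DomainTally(frame.loc[list(BASE_ROWS)])
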