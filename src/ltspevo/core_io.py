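"""Domain types and readers/writers for LTSP clone-resequencing analyses.

The central objects are per-clone mutation calls (one row per mutation per
clone, as produced by tabulating a variant caller's output across a clone
collection), the clones themselves, and protein-coding gene models used for
locus assignment and synonymous/non-synonymous site counting.

Coordinates are 1-based inclusive throughout, following GenBank convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

MUTATION_CLASSES = {"SNP", "small_indel", "large_deletion", "amplification", "mobile_element"}
CODING_EFFECTS = {"synonymous", "nonsynonymous", "noncoding", "indel_or_structural"}

#: Genes whose mutation marks a clone as a mutator (mismatch repair + proofreading).
DEFAULT_MUTATOR_GENES = ("mutS", "mutL", "mutH", "dnaQ")

#: Default column names of the mutation-table TSV dialect.
DEFAULT_SCHEMA = {
    "clone_id": "clone_id",
    "population": "population",
    "day": "day",
    "position": "position",
    "ref": "ref",
    "alt": "alt",
    "class": "class",
    "gene": "gene",
    "effect": "effect",
}


@dataclass
class MutationRecord:
    """A single mutation call in a single clone."""

    clone_id: str
    population: str
    day: int
    position: int
    ref_allele: str
    alt_allele: str
    mutation_class: str
    locus_id: str | None = None
    coding_effect: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")
        if self.mutation_class == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP records need single-base ref and alt")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNP ref and alt alleles must differ")

    @property
    def key(self) -> tuple[int, str, str]:
        """Identity of the mutation irrespective of carrier clone."""
        return (self.position, self.ref_allele, self.alt_allele)

    @property
    def label(self) -> str:
        return f"{self.position}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class Clone:
    """A sequenced isolate: one colony picked at one sampling day."""

    clone_id: str
    population: str
    day: int
    mutations: list[MutationRecord] = field(default_factory=list)
    is_mutator: bool = False
    lineage_id: str | None = None

    @property
    def mutation_keys(self) -> set[tuple[int, str, str]]:
        return {m.key for m in self.mutations}

    @property
    def loci(self) -> set[str]:
        return {m.locus_id for m in self.mutations if m.locus_id}


@dataclass
class GeneModel:
    """A protein-coding gene: strand, coding intervals and 5'->3' CDS sequence.

    ``intervals`` are 1-based inclusive (start, end) pairs in genome order.
    ``sequence`` is the concatenated coding sequence read 5'->3' (i.e. already
    reverse-complemented for minus-strand genes).
    """

    gene_id: str
    strand: str  # "+" or "-"
    intervals: list[tuple[int, int]]
    sequence: str
    upstream_interval: tuple[int, int] | None = None

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


@dataclass
class SiteCounts:
    """Expected numbers of non-synonymous and synonymous sites."""

    n_sites: float
    s_sites: float
    scope: str = "genome"

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.n_sites + other.n_sites, self.s_sites + other.s_sites, "genome")


class FunctionalPairTable:
    """Set of unordered locus pairs with a known functional association."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[frozenset[str]] = set()
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-pair {a!r} not allowed")
        self._pairs.add(frozenset((a, b)))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        for p in sorted(tuple(sorted(fp)) for fp in self._pairs):
            yield p


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def read_mutation_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    clone_manifest: str | Path | None = None,
) -> tuple[list[MutationRecord], list[Clone]]:
    """Read a per-clone mutation table (TSV) into records and aggregated clones.

    Parameters
    ----------
    path:
        Tab-separated table, one row per mutation call per clone.
    schema:
        Optional mapping from canonical column roles (``clone_id``,
        ``population``, ``day``, ``position``, ``ref``, ``alt``, ``class``,
        optionally ``gene`` and ``effect``) to the file's column names.
        Tables exported from different callers use different headers.
    clone_manifest:
        Optional TSV with columns clone_id/population/day listing every
        sequenced clone. Clones present here but absent from the mutation
        table are retained as mutation-free clones (they matter for
        frequency denominators).

    Returns
    -------
    (records, clones) with duplicated (clone, position, alt) rows collapsed.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["clone_id", "population", "day", "position", "ref", "alt", "class"]
    for role in required:
        if colmap[role] not in df.columns:
            raise SchemaError(f"required column {colmap[role]!r} (role {role!r}) missing from {path}")

    records: list[MutationRecord] = []
    seen: set[tuple[str, int, str]] = set()
    n_dup = 0
    for i, row in enumerate(df.to_dict("records"), start=2):  # header is line 1
        try:
            position = int(row[colmap["position"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {i}: malformed coordinate {row[colmap['position']]!r}") from exc
        ref = "" if pd.isna(row[colmap["ref"]]) else str(row[colmap["ref"]])
        alt = "" if pd.isna(row[colmap["alt"]]) else str(row[colmap["alt"]])
        clone_id = str(row[colmap["clone_id"]])
        dedup_key = (clone_id, position, alt)
        if dedup_key in seen:
            n_dup += 1
            continue
        seen.add(dedup_key)
        rec = MutationRecord(
            clone_id=clone_id,
            population=str(row[colmap["population"]]),
            day=int(row[colmap["day"]]),
            position=position,
            ref_allele=ref,
            alt_allele=alt,
            mutation_class=str(row[colmap["class"]]),
            locus_id=_opt(row, colmap.get("gene"), df.columns),
            coding_effect=_opt(row, colmap.get("effect"), df.columns),
        )
        records.append(rec)
    if n_dup:
        logger.warning("collapsed %d duplicated mutation rows in %s", n_dup, path)

    clones: dict[str, Clone] = {}
    for rec in records:
        clone = clones.get(rec.clone_id)
        if clone is None:
            clone = Clone(rec.clone_id, rec.population, rec.day)
            clones[rec.clone_id] = clone
        clone.mutations.append(rec)

    if clone_manifest is not None:
        manifest = pd.read_csv(clone_manifest, sep="\t", dtype=str)
        for row in manifest.itertuples(index=False):
            cid = str(row.clone_id)
            if cid not in clones:
                clones[cid] = Clone(cid, str(row.population), int(row.day))

    return records, sorted(clones.values(), key=lambda c: (c.population, c.day, c.clone_id))


def _opt(row: Mapping[str, object], col: str | None, columns) -> str | None:
    if col is None or col not in columns:
        return None
    val = row[col]
    if val is None or (isinstance(val, float) and pd.isna(val)) or pd.isna(val):
        return None
    return str(val)


def flag_mutators(clones: Iterable[Clone], mutator_genes: Sequence[str] = DEFAULT_MUTATOR_GENES) -> None:
    """Set ``is_mutator`` on clones carrying a mutation in any mutator gene.

    Requires locus assignment (``MutationRecord.locus_id``) to have run, or a
    gene column present in the input table.
    """
    genes = set(mutator_genes)
    for clone in clones:
        clone.is_mutator = any(m.locus_id in genes for m in clone.mutations)


def read_annotation(path: str | Path, fasta: str | Path | None = None) -> list[GeneModel]:
    """Read protein-coding gene models from GenBank or GFF3(+FASTA).

    GenBank flat files carry their own sequence; GFF3 input additionally
    needs the genome FASTA. Genes whose CDS length is not a multiple of 3
    (pseudogenes, annotation artifacts) are skipped with a warning.
    Minus-strand sequences are reverse-complemented so the stored coding
    sequence reads 5'->3'.
    """
    path = Path(path)
    if path.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank"}:
        return _read_genbank(path)
    if fasta is None:
        raise ValueError("GFF3 input requires the genome FASTA")
    return _read_gff3(path, fasta)


def _read_genbank(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        genome = str(rec.seq)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            gene_id = (feat.qualifiers.get("gene") or feat.qualifiers.get("locus_tag") or ["?"])[0]
            strand = "-" if feat.location.strand == -1 else "+"
            intervals = sorted(
                (int(part.start) + 1, int(part.end)) for part in feat.location.parts
            )
            model = _make_gene(gene_id, strand, intervals, genome)
            if model is not None:
                genes.append(model)
    return genes


def _read_gff3(path: Path, fasta: str | Path) -> list[GeneModel]:
    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    gff = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
        dtype={"start": int, "end": int},
    )
    cds = gff[gff["type"] == "CDS"]
    genes: list[GeneModel] = []
    grouped: dict[str, list] = {}
    for row in cds.itertuples(index=False):
        attrs = dict(kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv)
        gene_id = attrs.get("gene") or attrs.get("ID") or attrs.get("Parent") or "?"
        grouped.setdefault(gene_id, []).append(row)
    for gene_id, rows in grouped.items():
        seq = genome[rows[0].seqid]
        strand = rows[0].strand
        intervals = sorted((int(r.start), int(r.end)) for r in rows)
        model = _make_gene(gene_id, strand, intervals, seq)
        if model is not None:
            genes.append(model)
    genes.sort(key=lambda g: g.start)
    return genes


def _make_gene(gene_id: str, strand: str, intervals: list[tuple[int, int]], genome: str) -> GeneModel | None:
    seq = "".join(genome[s - 1 : e] for s, e in intervals)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    if len(seq) % 3 != 0:
        logger.warning("skipping gene %s: CDS length %d not divisible by 3", gene_id, len(seq))
        return None
    return GeneModel(gene_id=gene_id, strand=strand, intervals=intervals, sequence=seq)


def read_functional_pairs(path: str | Path) -> FunctionalPairTable:
    """Read a two-column TSV of functionally associated locus pairs."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return FunctionalPairTable((str(a), str(b)) for a, b in zip(df[0], df[1]))


def write_functional_pairs(table: FunctionalPairTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in table:
            fh.write(f"{a}\t{b}\n")


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write result tables to ``outdir``; Muller tables as CSV, the rest TSV.

    Re-reading any emitted table with :func:`read_result` reproduces the
    in-memory values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        sep, suffix = ("," , ".csv") if "muller" in name else ("\t", ".tsv")
        path = outdir / f"{name}{suffix}"
        df.to_csv(path, sep=sep, index=False)
        paths[name] = path
    return paths


def read_result(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep="," if path.suffix == ".csv" else "\t")
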