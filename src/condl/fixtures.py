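"""Packaged reference fixtures: curated tables and the worked-example parse.

Ships machine-readable transcriptions of the study's curated result
tables — the 32 centrality-selected genes with their per-metric top-20
flags, and the 28 vaccines with their associated gene lists — plus the
worked-example sentence with its dependency parse, a default
interaction-keyword list, and a small demonstration gene dictionary.
Packaged files are integrity-checked against embedded SHA-256 digests.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .corpus import (
    GeneDictionary,
    GeneMention,
    SentenceParse,
    load_gene_dictionary,
    load_keywords,
)

__all__ = [
    "Table1Row",
    "Table2Row",
    "FixtureIntegrityError",
    "load_table1",
    "load_table2",
    "table2_gene_sets",
    "central_genes",
    "worked_example_sentence",
    "WORKED_EXAMPLE_PATHS",
    "default_keywords",
    "demo_gene_dictionary",
    "export_fixtures",
]

_CHECKSUMS = {
    "table1.tsv": "b13a0c925d2ce6c91997f2492cec24be1733bc6d81d218bdad201030b988df18",
    "table2.tsv": "5507f834e872a2963b17bba1045b4b4d9ca2d31ab08587075c8d695bc8f8606c",
}

_DATA_FILES = (
    "table1.tsv",
    "table2.tsv",
    "worked_example.json",
    "interaction_keywords.txt",
    "demo_gene_dictionary.tsv",
)

SEED_GENE = "IFNG"


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


def _data_path(name: str) -> Path:
    path = resources.files("condl.data").joinpath(name)
    expected = _CHECKSUMS.get(name)
    if expected is not None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != expected:
            raise FixtureIntegrityError(
                f"fixture {name} is corrupted (sha256 {digest} != {expected})"
            )
    return Path(str(path))


@dataclass(frozen=True)
class Table1Row:
    """A centrality-selected gene: per-metric top-20 flags and grouping.

    ``star`` encodes the study's grouping — "" for genes ranked high in
    both the concept and concept+ontology networks, "*" for genes ranked
    high only with ontology support, "**" for genes found only with
    ontology support.
    """

    gene: str
    degree: bool
    eigenvector: bool
    betweenness: bool
    closeness: bool
    star: str
    reference_pmid: str

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "degree": self.degree,
            "eigenvector": self.eigenvector,
            "betweenness": self.betweenness,
            "closeness": self.closeness,
        }


@dataclass(frozen=True)
class Table2Row:
    """A vaccine with its ontology category and associated central genes."""

    vaccine: str
    category: str
    genes: tuple[str, ...]


def load_table1() -> list[Table1Row]:
    """The 32 centrality-selected genes (seed gene excluded by design)."""
    rows: list[Table1Row] = []
    with open(_data_path("table1.tsv"), encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, d, e, b, c, star, pmid = line.split("\t")
            rows.append(
                Table1Row(
                    gene=gene,
                    degree=d == "+",
                    eigenvector=e == "+",
                    betweenness=b == "+",
                    closeness=c == "+",
                    star=star,
                    reference_pmid=pmid,
                )
            )
    if len(rows) != 32:
        raise FixtureIntegrityError(f"expected 32 central genes, got {len(rows)}")
    if any(not any(r.flags.values()) for r in rows):
        raise FixtureIntegrityError("every central gene needs >=1 top-20 flag")
    if any(r.gene == SEED_GENE for r in rows):
        raise FixtureIntegrityError("the seed gene must not appear in the ranking")
    return rows


def load_table2() -> list[Table2Row]:
    """The 28 vaccines associated with the central genes."""
    rows: list[Table2Row] = []
    with open(_data_path("table2.tsv"), encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            vaccine, category, count, genes = line.split("\t")
            gene_tuple = tuple(g.strip() for g in genes.split(",") if g.strip())
            if int(count) != len(gene_tuple):
                raise FixtureIntegrityError(
                    f"{vaccine}: listed gene count {count} != {len(gene_tuple)}"
                )
            rows.append(Table2Row(vaccine=vaccine, category=category, genes=gene_tuple))
    if len(rows) != 28:
        raise FixtureIntegrityError(f"expected 28 vaccines, got {len(rows)}")
    allowed = {r.gene for r in load_table1()} | {SEED_GENE}
    for row in rows:
        unknown = set(row.genes) - allowed
        if unknown:
            raise FixtureIntegrityError(
                f"{row.vaccine}: genes outside the central set: {sorted(unknown)}"
            )
    return rows


def table2_gene_sets() -> dict[str, set[str]]:
    """Vaccine label -> set of associated gene symbols."""
    return {row.vaccine: set(row.genes) for row in load_table2()}


def central_genes(include_seed: bool = False) -> set[str]:
    """The 32 centrality-selected gene symbols (optionally plus the seed)."""
    genes = {r.gene for r in load_table1()}
    if include_seed:
        genes.add(SEED_GENE)
    return genes


#: shortest dependency paths stated for the worked-example sentence, keyed
#: by the unordered surface pair; the remaining three pairs are
#: non-interacting in that sentence.
WORKED_EXAMPLE_PATHS: dict[frozenset[str], tuple[str, ...]] = {
    frozenset({"IFN-alpha", "IL-12"}): (
        "nominal-subject",
        "up-regulated",
        "direct-object",
    ),
    frozenset({"IFN-alpha", "TNF-alpha"}): (
        "nominal-subject",
        "up-regulated",
        "direct-object",
        "IL-12",
        "conjunct-and",
    ),
    frozenset({"IFN-alpha", "IL-10"}): (
        "nominal-subject",
        "up-regulated",
        "conjunct-and",
        "down-regulated",
        "direct-object",
    ),
}


def worked_example_sentence() -> SentenceParse:
    """The worked-example sentence with its dependency parse and mentions."""
    with open(_data_path("worked_example.json"), encoding="utf-8") as fh:
        rec = json.load(fh)
    return SentenceParse(
        document_id=rec["document_id"],
        sentence_index=rec["sentence_index"],
        tokens=tuple(rec["tokens"]),
        dep_edges=tuple((h, d, label) for h, d, label in rec["dep_edges"]),
        mentions=tuple(
            GeneMention(start=m["start"], end=m["end"], surface=m["surface"])
            for m in rec["mentions"]
        ),
    )


def default_keywords() -> list[str]:
    """The packaged interaction-keyword list."""
    return load_keywords(_data_path("interaction_keywords.txt"))


def demo_gene_dictionary() -> GeneDictionary:
    """A small symbol/synonym dictionary covering the curated gene set."""
    return load_gene_dictionary(_data_path("demo_gene_dictionary.tsv"))


_TABLE1_HEADER = "# gene\tdegree\teigenvector\tbetweenness\tcloseness\tstar\treference_pmid"
_TABLE2_HEADER = "# vaccine\tcategory\tnum_genes\tgenes"


def write_table1(rows: list[Table1Row], path: str | Path) -> None:
    """Serialize centrality-flag rows back to the packaged TSV dialect."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_TABLE1_HEADER + "\n")
        for r in rows:
            flags = "\t".join(
                "+" if r.flags[m] else "-"
                for m in ("degree", "eigenvector", "betweenness", "closeness")
            )
            fh.write(f"{r.gene}\t{flags}\t{r.star}\t{r.reference_pmid}\n")


def write_table2(rows: list[Table2Row], path: str | Path) -> None:
    """Serialize vaccine/gene-list rows back to the packaged TSV dialect."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_TABLE2_HEADER + "\n")
        for r in rows:
            fh.write(
                f"{r.vaccine}\t{r.category}\t{len(r.genes)}\t{','.join(r.genes)}\n"
            )


def export_fixtures(out_dir: str | Path) -> list[Path]:
    """Copy every packaged fixture file into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in _DATA_FILES:
        dst = out / name
        shutil.copyfile(_data_path(name), dst)
        written.append(dst)
    return written
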