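"""Readers and writers for the formats the pipeline touches.

OBO taxonomies load through :func:`tafi.taxonomy.load_taxonomy`; this
module covers gene→term annotations (GAF 2.x or two-column TSV), gene
sets (GMT, plain lists), module trees (Newick via scikit-bio), and the
YAML run configuration.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml
from skbio import TreeNode

from .modules import AnnotatedModule, ModuleError, ModuleTree
from .taxonomy import Taxonomy, TermSet

__all__ = [
    "read_annotations",
    "write_annotations_tsv",
    "read_gene_list",
    "read_gmt",
    "write_gmt",
    "read_newick",
    "write_newick",
    "read_modules",
    "write_obo",
    "RunConfig",
]

logger = logging.getLogger(__name__)


# -- annotations -----------------------------------------------------------


def read_annotations(
    path: str,
    taxonomy: Taxonomy,
    *,
    use_symbol: bool = False,
    strict: bool = False,
) -> dict[str, TermSet]:
    """Load gene→term annotations from a GAF 2.x file or a two-column TSV.

    GAF rows with a NOT qualifier are skipped; the gene identifier is the
    DB object ID (column 2) or, with ``use_symbol``, the symbol (column
    3).  Unknown term IDs are skipped with a warning (``strict`` raises);
    alternate IDs from the OBO load are mapped to their primary term.
    Each gene's terms are reduced to unrelated form.
    """
    with open(path) as fh:
        text = fh.read()
    is_gaf = text.startswith("!") or path.endswith((".gaf", ".gaf.txt"))
    raw: dict[str, set[str]] = {}
    alt = getattr(taxonomy, "alt_ids", {})
    skipped: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("!", "#")):
            continue
        cols = line.split("\t")
        if is_gaf:
            if len(cols) < 5:
                raise ModuleError(f"{path}:{lineno}: GAF row has {len(cols)} columns")
            if "NOT" in cols[3].split("|"):
                continue
            gene = cols[2] if use_symbol else cols[1]
            term = cols[4]
        else:
            if len(cols) < 2:
                raise ModuleError(f"{path}:{lineno}: expected gene<TAB>term")
            gene, term = cols[0].strip(), cols[1].strip()
        term = alt.get(term, term)
        if term not in taxonomy:
            if strict:
                raise ModuleError(f"{path}:{lineno}: unknown term {term!r}")
            skipped.add(term)
            continue
        raw.setdefault(gene, set()).add(term)
    if skipped:
        warnings.warn(f"{path}: skipped {len(skipped)} unknown term IDs")
    if not raw:
        warnings.warn(f"{path}: no annotations loaded")
    return {g: taxonomy.reduce_to_unrelated(ts) for g, ts in sorted(raw.items())}


def write_annotations_tsv(
    annotations: Mapping[str, Iterable[str]], path: str, *, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


# -- gene sets -------------------------------------------------------------


def read_gene_list(path: str) -> list[str]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split()[0])
    return genes


def read_gmt(path: str) -> list[tuple[str, str, set[str]]]:
    """GMT rows as (name, description, gene set); one module per line."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ModuleError(f"{path}:{lineno}: GMT needs name, description, genes")
            out.append((cols[0], cols[1], {g for g in cols[2:] if g}))
    return out


def write_gmt(modules: Sequence[tuple[str, str, Iterable[str]]], path: str) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in modules:
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# -- module trees (Newick) -------------------------------------------------


def _treenode_to_module(node: TreeNode) -> ModuleTree:
    children: dict[str, tuple[str, ...]] = {}
    leaf_genes: dict[str, str] = {}
    counter = [0]

    def walk(tn: TreeNode) -> str:
        counter[0] += 1
        nid = f"n{counter[0]}"
        if tn.is_tip():
            if not tn.name:
                raise ModuleError("Newick leaf without a name")
            children[nid] = ()
            leaf_genes[nid] = tn.name
        else:
            children[nid] = tuple(walk(c) for c in tn.children)
        return nid

    root = walk(node)
    return ModuleTree(root=root, children=children, leaf_genes=leaf_genes)


def read_newick(path: str) -> list[ModuleTree]:
    """Read one or more Newick trees (one per ';'-terminated statement)."""
    with open(path) as fh:
        text = "\n".join(
            line for line in fh.read().splitlines() if not line.startswith("#")
        )
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    trees = []
    for i, chunk in enumerate(chunks):
        try:
            tn = TreeNode.read(_io.StringIO(chunk + ";"), format="newick")
        except Exception as exc:  # scikit-bio raises format-specific errors
            raise ModuleError(f"{path}: malformed Newick in tree {i + 1}: {exc}") from exc
        trees.append(_treenode_to_module(tn))
    if not trees:
        raise ModuleError(f"{path}: no trees found")
    return trees


def _module_to_treenode(tree: ModuleTree, annotation: Mapping[str, TermSet] | None) -> TreeNode:
    def build(node: str) -> TreeNode:
        kids = tree.children[node]
        if not kids:
            return TreeNode(name=tree.leaf_genes[node])
        name = None
        if annotation and node in annotation:
            name = "|".join(sorted(annotation[node]))
        return TreeNode(name=name, children=[build(c) for c in kids])

    return build(tree.root)


def write_newick(
    modules: Sequence[ModuleTree | AnnotatedModule],
    path: str,
    *,
    label_internal: bool = True,
    header: str | None = None,
) -> None:
    """Serialize a forest as multi-tree Newick.

    Internal nodes of annotated modules are labelled with their
    pipe-joined term sets when ``label_internal`` is set.
    """
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for item in modules:
            if isinstance(item, AnnotatedModule):
                tree, ann = item.tree, (item.annotation if label_internal else None)
            else:
                tree, ann = item, None
            tn = _module_to_treenode(tree, ann)
            buf = _io.StringIO()
            tn.write(buf, format="newick")
            fh.write(buf.getvalue())


def read_modules(path: str) -> list[tuple[str, set[str]]] | list[ModuleTree]:
    """Dispatch on content: GMT → bags of genes, Newick → fixed hierarchies."""
    with open(path) as fh:
        head = fh.read(2048).lstrip()
    if head.startswith("("):
        return read_newick(path)
    return [(name, genes) for name, _, genes in read_gmt(path)]


# -- OBO output (for the synthetic generators) -----------------------------


def write_obo(taxonomy: Taxonomy, path: str, *, remark: str | None = None) -> None:
    """Minimal OBO 1.2 serialization (id / name / is_a), obonet-compatible."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: synthetic-taxonomy\n")
        if remark:
            fh.write(f"remark: {remark}\n")
        fh.write("\n")
        for term in sorted(taxonomy.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            for parent in sorted(taxonomy.graph.predecessors(term)):
                fh.write(f"is_a: {parent} ! {parent}\n")
            fh.write("\n")


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Serializable bundle of paths and parameters for a pipeline run."""

    taxonomy_path: str = ""
    annotations_path: str = ""
    modules_path: str = ""
    background_path: str = ""
    output_dir: str = "."
    theta: float = 10.0
    penalty_variant: str = "reciprocal"
    alpha: float = 0.9
    beta: float = 0.1
    n_samples: int = 1000
    seed: int = 0
    alpha_level: float = 0.05
    log_level: str = "INFO"

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
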