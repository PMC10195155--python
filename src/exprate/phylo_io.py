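"""Trees and expression tables: reading, validation, and result writers.

Input conventions
-----------------
* Trees are rooted, bifurcating, ultrametric Newick with branch lengths in
  time units (e.g. millions of years).  Ultrametricity is checked to a
  relative tolerance of 1e-6 and can be disabled for non-ultrametric gene
  trees.
* Expression tables are tab-delimited.  The header row names the species
  (matching the tree's tip labels) plus optional metadata columns: a gene
  identifier column (``GENE``/``GENEID``/``ID``), a description column
  (``DESC``/``DESCRIPTION``) and a ``SAMPLETYPE`` column assigning each gene
  row to a sample group.  Metadata column names are matched
  case-insensitively; every other header cell is a species.  Cells equal to
  ``-``, ``?`` or ``N`` mark missing measurements.  Values are linear,
  non-negative expression levels (e.g. TPM).

Node numbering is deterministic: the root is node 0 and ids are assigned in
preorder (parents before children, children in Newick order), so every
branch is addressable by its child node's id in all outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "ExpressionTable",
    "TreeValidationError",
    "TableValidationError",
    "NewickFormatError",
    "read_newick",
    "parse_newick",
    "read_expression_table",
    "write_expression_table",
    "write_results",
]

MISSING_TOKENS = {"-", "?", "N"}
_GENE_HEADERS = {"GENE", "GENEID", "ID"}
_DESC_HEADERS = {"DESC", "DESCRIPTION"}
_SAMPLE_HEADER = "SAMPLETYPE"
DEFAULT_SAMPLE = "default"

ULTRAMETRIC_RTOL = 1e-6


class NewickFormatError(ValueError):
    """Raised when a tree file cannot be parsed as Newick."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the model's requirements."""


class TableValidationError(ValueError):
    """Raised for malformed or inconsistent expression tables."""


@dataclass(frozen=True)
class PhyloTree:
    """A rooted bifurcating tree with branch lengths.

    Nodes are integers ``0..n_nodes-1``; the root is 0 and ids follow a
    preorder traversal.  ``parent[root] == -1`` and ``lengths[root] == 0``.
    Branches are identified by their child node id (``1..n_nodes-1``; a
    bifurcating rooted tree on ``n`` tips has ``2n - 2`` branches).
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: tuple
    children: tuple

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    @property
    def tips(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def internal_nodes(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.children[v]]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tips]

    @property
    def branches(self) -> list[int]:
        """Branch ids = every non-root node id."""
        return list(range(1, self.n_nodes))

    def postorder(self) -> list[int]:
        order: list[int] = []

        def visit(v: int) -> None:
            for c in self.children[v]:
                visit(c)
            order.append(v)

        visit(self.root)
        return order

    def preorder(self) -> list[int]:
        return list(range(self.n_nodes))

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    @property
    def depth(self) -> float:
        """Root-to-tip height (mean over tips; equals any tip's depth when
        ultrametric)."""
        d = self.depths()
        return float(np.mean([d[t] for t in self.tips]))

    def tip_index(self) -> dict[str, int]:
        return {self.labels[v]: v for v in self.tips}

    def mrca(self, tip_names: Sequence[str]) -> int:
        idx = self.tip_index()
        try:
            nodes = [idx[name] for name in tip_names]
        except KeyError as exc:
            raise TreeValidationError(f"unknown tip label {exc.args[0]!r}") from exc

        def ancestors(v: int) -> list[int]:
            path = [v]
            while self.parent[path[-1]] >= 0:
                path.append(int(self.parent[path[-1]]))
            return path

        common = set(ancestors(nodes[0]))
        for v in nodes[1:]:
            common &= set(ancestors(v))
        # deepest common ancestor = max preorder id among common ancestors'
        # ... ids are preorder so the deepest is the largest id on the path
        return max(common, key=lambda u: len(self._path_to_root(u)))

    def _path_to_root(self, v: int) -> list[int]:
        path = [v]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def subtree_nodes(self, v: int) -> list[int]:
        out = [v]
        stack = list(self.children[v])
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return out

    def validate(self, require_ultrametric: bool = True) -> None:
        tips = self.tips
        names = [self.labels[v] for v in tips]
        if any(not n for n in names):
            raise TreeValidationError("every tip must carry a non-empty label")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for v in self.internal_nodes:
            if len(self.children[v]) != 2:
                raise TreeValidationError(
                    f"tree must be bifurcating; node {v} has "
                    f"{len(self.children[v])} children"
                )
        for v in range(1, self.n_nodes):
            if not np.isfinite(self.lengths[v]) or self.lengths[v] < 0:
                raise TreeValidationError(f"branch above node {v} has invalid length")
        if require_ultrametric:
            d = self.depths()
            tip_depths = np.array([d[t] for t in tips])
            ref = float(np.median(tip_depths))
            scale = max(tip_depths.max(), 1.0)
            dev = np.abs(tip_depths - ref)
            if (dev > ULTRAMETRIC_RTOL * scale).any():
                worst = tips[int(np.argmax(dev))]
                raise TreeValidationError(
                    f"tree is not ultrametric: tip {self.labels[worst]!r} has "
                    f"root-to-tip distance {d[worst]:g} vs {ref:g}"
                )

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                body = self.labels[v]
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if v == self.root:
                return body
            return f"{body}:{self.lengths[v]:.10g}"

        return fmt(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    parent: list[int] = []
    lengths: list[float] = []
    labels: list[str] = []
    children: list[list[int]] = []

    def add(node, parent_id: int) -> int:
        vid = len(parent)
        parent.append(parent_id)
        bl = node.edge.length
        if parent_id >= 0:
            if bl is None:
                raise TreeValidationError(
                    "every non-root branch must have a branch length"
                )
            lengths.append(float(bl))
        else:
            lengths.append(0.0)
        if node.taxon is not None:
            labels.append(str(node.taxon.label))
        elif node.is_leaf():
            labels.append("" if node.label is None else str(node.label))
        else:
            labels.append("" if node.label is None else str(node.label))
        children.append([])
        for child in node.child_nodes():
            cid = add(child, vid)
            children[vid].append(cid)
        return vid

    add(dtree.seed_node, -1)
    return PhyloTree(
        parent=np.asarray(parent, dtype=int),
        lengths=np.asarray(lengths, dtype=float),
        labels=tuple(labels),
        children=tuple(tuple(c) for c in children),
    )


def parse_newick(newick: str, require_ultrametric: bool = True) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise NewickFormatError(f"could not parse Newick tree: {exc}") from exc
    tree = _from_dendropy(dtree)
    tree.validate(require_ultrametric=require_ultrametric)
    return tree


def read_newick(path: str | Path, require_ultrametric: bool = True) -> PhyloTree:
    """Read a rooted ultrametric Newick tree with branch lengths."""
    text = Path(path).read_text()
    if not text.strip():
        raise NewickFormatError(f"{path}: empty tree file")
    return parse_newick(text, require_ultrametric=require_ultrametric)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Gene x species matrix of linear expression values with a missing mask.

    ``values[i, j]`` is the expression of gene ``i`` in species
    ``species[j]`` (non-negative; entries under ``missing`` are undefined and
    stored as NaN).  ``samples[i]`` tags the row's sample group; the same
    gene id may recur across samples but ``(gene_id, sample)`` is unique.
    """

    gene_ids: list[str]
    samples: list[str]
    descriptions: list[str]
    species: list[str]
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        g, s = self.values.shape
        if self.missing.shape != (g, s) or len(self.species) != s:
            raise TableValidationError("inconsistent table dimensions")
        if len(self.gene_ids) != g or len(self.samples) != g or len(self.descriptions) != g:
            raise TableValidationError("inconsistent gene metadata lengths")
        keys = list(zip(self.gene_ids, self.samples))
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise TableValidationError(f"duplicate (gene, sample) rows: {dupes[:5]}")
        observed = self.values[~self.missing]
        if observed.size and (np.nanmin(observed) < 0 or not np.all(np.isfinite(observed))):
            raise TableValidationError("expression values must be finite and >= 0")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def sample_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s)
        return list(seen)

    def max_value(self) -> float:
        obs = self.values[~self.missing]
        if obs.size == 0:
            raise TableValidationError("table has no observed values")
        return float(obs.max())

    def subset(self, rows: Iterable[int]) -> "ExpressionTable":
        rows = list(rows)
        return ExpressionTable(
            gene_ids=[self.gene_ids[i] for i in rows],
            samples=[self.samples[i] for i in rows],
            descriptions=[self.descriptions[i] for i in rows],
            species=list(self.species),
            values=self.values[rows],
            missing=self.missing[rows],
        )

    def by_sample(self) -> dict[str, "ExpressionTable"]:
        out = {}
        for name in self.sample_names:
            rows = [i for i, s in enumerate(self.samples) if s == name]
            out[name] = self.subset(rows)
        return out


def _classify_header(cells: list[str]) -> tuple[int | None, int | None, int | None, list[int]]:
    gene_col = desc_col = sample_col = None
    species_cols: list[int] = []
    for j, cell in enumerate(cells):
        up = cell.strip().upper()
        if up in _GENE_HEADERS and gene_col is None:
            gene_col = j
        elif up in _DESC_HEADERS and desc_col is None:
            desc_col = j
        elif up == _SAMPLE_HEADER and sample_col is None:
            sample_col = j
        else:
            species_cols.append(j)
    return gene_col, desc_col, sample_col, species_cols


def read_expression_table(path: str | Path, tree: PhyloTree) -> ExpressionTable:
    """Read a tab-delimited expression table and align it to ``tree``.

    Cells equal to ``-``, ``?`` or ``N`` are recorded as missing.  Species
    columns must match the tree's tips exactly (any order).
    """
    text = Path(path).read_text()
    return parse_expression_table(text, tree)


def parse_expression_table(text: str, tree: PhyloTree) -> ExpressionTable:
    lines = [ln.rstrip("\n").rstrip("\r") for ln in text.splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise TableValidationError("empty expression table")
    header = [c.strip() for c in lines[0].split("\t")]
    gene_col, desc_col, sample_col, species_cols = _classify_header(header)
    species = [header[j] for j in species_cols]
    tree_tips = set(tree.tip_labels)
    extra = sorted(set(species) - tree_tips)
    absent = sorted(tree_tips - set(species))
    if extra or absent:
        raise TableValidationError(
            f"species columns do not match tree tips "
            f"(not in tree: {extra}; missing from table: {absent})"
        )

    gene_ids: list[str] = []
    samples: list[str] = []
    descriptions: list[str] = []
    rows: list[list[float]] = []
    mask: list[list[bool]] = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in ln.split("\t")]
        if len(cells) != len(header):
            raise TableValidationError(
                f"line {i}: expected {len(header)} tab-separated fields, got {len(cells)}"
            )
        gene_ids.append(cells[gene_col] if gene_col is not None else f"gene{i - 1}")
        descriptions.append(cells[desc_col] if desc_col is not None else "")
        samples.append(cells[sample_col] if sample_col is not None else DEFAULT_SAMPLE)
        vals: list[float] = []
        miss: list[bool] = []
        for j in species_cols:
            cell = cells[j]
            if cell in MISSING_TOKENS:
                vals.append(np.nan)
                miss.append(True)
                continue
            try:
                x = float(cell)
            except ValueError as exc:
                raise TableValidationError(
                    f"line {i}, column {header[j]!r}: cannot parse {cell!r}"
                ) from exc
            if x < 0:
                raise TableValidationError(
                    f"line {i}, column {header[j]!r}: negative expression {x}"
                )
            vals.append(x)
            miss.append(False)
        rows.append(vals)
        mask.append(miss)

    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(species)))
    missing = np.asarray(mask, dtype=bool) if mask else np.empty((0, len(species)), bool)
    return ExpressionTable(
        gene_ids=gene_ids,
        samples=samples,
        descriptions=descriptions,
        species=species,
        values=values,
        missing=missing,
    )


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    """Write a table in the tab-delimited input format (missing cells as '-')."""
    with open(path, "w") as fh:
        cols = ["GENE", "SAMPLETYPE"] + list(table.species)
        fh.write("\t".join(cols) + "\n")
        for i in range(table.n_genes):
            cells = [table.gene_ids[i], table.samples[i]]
            for j in range(len(table.species)):
                if table.missing[i, j]:
                    cells.append("-")
                else:
                    cells.append(repr(float(table.values[i, j])))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------


def _node_display(tree: PhyloTree, v: int) -> str:
    return tree.labels[v] if tree.labels[v] else f"<{v}>"


def _annotated_newick(tree: PhyloTree, note: dict[int, str]) -> str:
    """Newick with per-node `[&...]` comment annotations."""

    def fmt(v: int) -> str:
        if not tree.children[v]:
            body = tree.labels[v] + note.get(v, "")
        else:
            body = "(" + ",".join(fmt(c) for c in tree.children[v]) + ")" + f"{v}" + note.get(v, "")
        if v == tree.root:
            return body
        return f"{body}:{tree.lengths[v]:.10g}"

    return fmt(tree.root) + ";"


def write_results(fit, recon, out_prefix: str | Path) -> list[Path]:
    """Write the four standard outputs for a fitted model + reconstruction.

    Produces ``<prefix>_ancestral_states.tsv`` (per gene x node point
    estimates and 95% credible bounds, on both log and linear scales),
    ``<prefix>_change_summary.tsv`` (per-branch tallies of increases,
    decreases and credible changes over genes), ``<prefix>_asr.nex`` (NEXUS
    trees, one per gene, nodes annotated ``[&state=..,lo=..,hi=..]`` with
    linear-scale values) and ``<prefix>_model.txt`` (σ² values and -lnL).

    ``fit`` may be an inference ``FitResult`` or ``None`` (reconstruction
    under fixed rates).  Returns the list of written paths.
    """
    from .reconstruction import call_changes, change_summary  # local: avoid cycle

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tree = recon.tree
    e_min = math.exp(recon.grid.x_min)

    asr_path = Path(f"{out_prefix}_ancestral_states.tsv")
    with open(asr_path, "w") as fh:
        fh.write(
            "gene\tsample\tnode\tnode_label\tstate_log\tci_lo_log\tci_hi_log\t"
            "state_linear\tci_lo_linear\tci_hi_linear\n"
        )
        for i, (gid, sample) in enumerate(zip(recon.gene_ids, recon.samples)):
            for v in range(tree.n_nodes):
                xs = recon.point[i, v]
                lo = recon.ci_lo[i, v]
                hi = recon.ci_hi[i, v]
                fh.write(
                    f"{gid}\t{sample}\t{v}\t{_node_display(tree, v)}\t"
                    f"{xs:.6f}\t{lo:.6f}\t{hi:.6f}\t"
                    f"{max(math.exp(xs) - e_min, 0.0):.6f}\t"
                    f"{max(math.exp(lo) - e_min, 0.0):.6f}\t"
                    f"{max(math.exp(hi) - e_min, 0.0):.6f}\n"
                )

    changes = call_changes(recon)
    summary = change_summary(changes, tree)
    summary_path = Path(f"{out_prefix}_change_summary.tsv")
    summary.to_csv(summary_path, sep="\t", index=False)

    nexus_path = Path(f"{out_prefix}_asr.nex")
    with open(nexus_path, "w") as fh:
        fh.write("#NEXUS\nBEGIN TREES;\n")
        for i, (gid, sample) in enumerate(zip(recon.gene_ids, recon.samples)):
            note = {}
            for v in range(tree.n_nodes):
                st = max(math.exp(recon.point[i, v]) - e_min, 0.0)
                lo = max(math.exp(recon.ci_lo[i, v]) - e_min, 0.0)
                hi = max(math.exp(recon.ci_hi[i, v]) - e_min, 0.0)
                note[v] = f"[&state={st:.6f},lo={lo:.6f},hi={hi:.6f}]"
            name = gid if sample == DEFAULT_SAMPLE else f"{gid}.{sample}"
            fh.write(f"  TREE {name} = {_annotated_newick(tree, note)}\n")
        fh.write("END;\n")

    model_path = Path(f"{out_prefix}_model.txt")
    with open(model_path, "w") as fh:
        if fit is not None:
            fh.write(f"model_kind\t{fit.rates.kind}\n")
            fh.write(f"n_params\t{fit.rates.n_params}\n")
            for k, val in enumerate(fit.rates.values):
                fh.write(f"sigma2_{k + 1}\t{val:.10g}\n")
            fh.write(f"neg_log_likelihood\t{fit.neg_log_lik:.10f}\n")
            fh.write(f"converged\t{fit.converged}\n")
            fh.write(f"n_evaluations\t{fit.n_evals}\n")
        else:
            fh.write(f"model_kind\t{recon.rates.kind}\n")
            for k, val in enumerate(recon.rates.values):
                fh.write(f"sigma2_{k + 1}\t{val:.10g}\n")
            if recon.log_lik is not None:
                fh.write(f"neg_log_likelihood\t{-recon.log_lik:.10f}\n")

    return [asr_path, summary_path, nexus_path, model_path]
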