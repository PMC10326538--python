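"""Readers and writers: Newick trees, loci containers, results tables.

Tip labels follow the convention ``P<pop>_<index>`` so a plain Newick string
carries the population assignment; a sidecar label-to-population mapping is
accepted as an alternative.  All tables are tab-separated text with a
versioned ``# imcoal-...`` header comment so schema drift is detected on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import pandas as pd

from .params import IMParams, PARAM_NAMES
from .simulate import ARGLocus
from .trees import GeneTree, parse_tip_label

__all__ = [
    "NewickError",
    "MalformedNewickError",
    "NonUltrametricError",
    "LabelConventionError",
    "SchemaError",
    "parse_newick",
    "write_newick",
    "read_trees",
    "write_trees",
    "write_loci",
    "read_loci",
    "write_results",
    "read_results",
    "read_ms_trees",
    "load_config",
]


class NewickError(ValueError):
    """Base class for tree-parsing failures."""


class MalformedNewickError(NewickError):
    """The string is not well-formed Newick with branch lengths."""


class NonUltrametricError(NewickError):
    """Root-to-tip distances disagree beyond tolerance."""


class LabelConventionError(NewickError):
    """A tip label does not resolve to a population."""


class SchemaError(ValueError):
    """A results table does not match its declared column schema."""


def parse_newick(
    text: str,
    pop_map: Optional[dict[str, int]] = None,
    tolerance: float = 1e-8,
) -> GeneTree:
    """Parse a Newick string into a validated :class:`~imcoal.trees.GeneTree`.

    Node times are reconstructed from root-to-tip path lengths; the tree must
    be binary and ultrametric within ``tolerance`` (relative to its depth).
    Populations come from ``pop_map`` when given, otherwise from the
    ``P<pop>_<index>`` label convention.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise MalformedNewickError(f"cannot parse Newick: {exc}") from exc
    root = dtree.seed_node
    depth: dict = {root: 0.0}
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise MalformedNewickError("every non-root edge needs a branch length")
        depth[node] = depth[node.parent_node] + float(node.edge.length)
    leaves = [n for n in dtree.leaf_node_iter()]
    if len(leaves) < 2:
        raise MalformedNewickError("need at least two tips")
    for node in dtree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            raise MalformedNewickError("tree must be strictly binary")
    height = max(depth[l] for l in leaves)
    tol = tolerance * max(1.0, height)
    if max(depth[l] for l in leaves) - min(depth[l] for l in leaves) > tol:
        raise NonUltrametricError(
            "root-to-tip distances differ beyond tolerance; tree is not ultrametric"
        )

    labels = sorted(
        (l.taxon.label if l.taxon else "" for l in leaves)
    )
    if len(set(labels)) != len(labels) or "" in labels:
        raise MalformedNewickError("tips must carry unique labels")
    pops = []
    for lab in labels:
        if pop_map is not None:
            if lab not in pop_map:
                raise LabelConventionError(f"no population for tip {lab!r}")
            pops.append(int(pop_map[lab]))
        else:
            try:
                pops.append(parse_tip_label(lab))
            except ValueError as exc:
                raise LabelConventionError(str(exc)) from exc

    tip_id = {lab: i for i, lab in enumerate(labels)}
    internal = sorted(
        dtree.preorder_internal_node_iter(), key=lambda n: height - depth[n]
    )
    node_id: dict = {}
    for l in leaves:
        node_id[l] = tip_id[l.taxon.label]
    events = []
    for j, node in enumerate(internal):
        node_id[node] = len(labels) + j
    for node in internal:
        a, b = node.child_nodes()
        events.append((height - depth[node], node_id[a], node_id[b]))
    try:
        return GeneTree.from_events(labels, pops, events)
    except ValueError as exc:
        raise NonUltrametricError(str(exc)) from exc


def write_newick(tree: GeneTree, precision: int = 12) -> str:
    return tree.to_newick(precision=precision)


def read_trees(
    path: Union[str, Path], pop_map: Optional[dict[str, int]] = None
) -> list[GeneTree]:
    """Read one Newick tree per non-empty line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(parse_newick(line, pop_map=pop_map))
    return out


def write_trees(trees: Sequence[GeneTree], path: Union[str, Path]) -> None:
    Path(path).write_text("".join(t.to_newick() + "\n" for t in trees))


# ---------------------------------------------------------------------------
# loci container: one line per non-recombined block
# ---------------------------------------------------------------------------

_LOCI_HEADER = "# imcoal-loci\tv1"
_LOCI_COLUMNS = ["locus_id", "block_start", "block_end", "newick"]


def write_loci(loci: Sequence[ARGLocus], path: Union[str, Path]) -> None:
    """Write loci as TSV: columns locus_id, block_start, block_end, newick."""
    lines = [_LOCI_HEADER, "\t".join(_LOCI_COLUMNS)]
    for i, locus in enumerate(loci):
        for start, end, tree in locus.blocks:
            lines.append(f"{i}\t{start!r}\t{end!r}\t{tree.to_newick()}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_loci(
    path: Union[str, Path], pop_map: Optional[dict[str, int]] = None
) -> list[ARGLocus]:
    text = Path(path).read_text().splitlines()
    if not text or text[0] != _LOCI_HEADER:
        raise SchemaError(f"not an imcoal loci file: {path}")
    if text[1].split("\t") != _LOCI_COLUMNS:
        raise SchemaError(f"unexpected loci columns in {path}")
    by_locus: dict[str, list[tuple[float, float, GeneTree]]] = {}
    order: list[str] = []
    for line in text[2:]:
        if not line.strip():
            continue
        locus_id, start, end, newick = line.split("\t")
        if locus_id not in by_locus:
            by_locus[locus_id] = []
            order.append(locus_id)
        by_locus[locus_id].append(
            (float(start), float(end), parse_newick(newick, pop_map=pop_map))
        )
    loci = []
    for locus_id in order:
        blocks = sorted(by_locus[locus_id], key=lambda b: b[0])
        breakpoints = tuple(b[0] for b in blocks[1:])
        loci.append(ARGLocus(breakpoints=breakpoints, blocks=tuple(blocks)))
    return loci


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

REPLICATES_SCHEMA = (
    ["rho", "replicate", "n_loci"]
    + list(PARAM_NAMES)
    + ["log_posterior", "converged", "error"]
)
SUMMARY_SCHEMA = [
    "rho",
    "n_loci",
    "parameter",
    "mean",
    "bias",
    "sd",
    "se",
    "n_replicates",
]
_RESULTS_SCHEMAS = {"replicates": REPLICATES_SCHEMA, "summary": SUMMARY_SCHEMA}


def write_results(
    table: pd.DataFrame, path: Union[str, Path], kind: str = "replicates"
) -> None:
    """Write a replicate-level or summary table as schema-versioned TSV."""
    schema = _RESULTS_SCHEMAS.get(kind)
    if schema is None:
        raise SchemaError(f"unknown results kind {kind!r}")
    if list(table.columns) != schema:
        raise SchemaError(
            f"table columns {list(table.columns)} do not match the "
            f"{kind} schema {schema}"
        )
    with open(path, "w") as fh:
        fh.write(f"# imcoal-results\tv1\tkind={kind}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_results(path: Union[str, Path]) -> tuple[pd.DataFrame, str]:
    """Read a results TSV; returns (table, kind) and validates the schema."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        parts = header.split("\t")
        if len(parts) != 3 or parts[0] != "# imcoal-results" or parts[1] != "v1":
            raise SchemaError(f"not an imcoal results file: {path}")
        kind = parts[2].removeprefix("kind=")
        if kind not in _RESULTS_SCHEMAS:
            raise SchemaError(f"unknown results kind {kind!r}")
        table = pd.read_csv(fh, sep="\t")
    if "error" in table.columns:
        table["error"] = table["error"].fillna("").astype(str)
    if list(table.columns) != _RESULTS_SCHEMAS[kind]:
        raise SchemaError(
            f"columns {list(table.columns)} do not match the {kind} schema"
        )
    return table, kind


# ---------------------------------------------------------------------------
# miscellaneous
# ---------------------------------------------------------------------------


def read_ms_trees(text: str) -> list[list[tuple[Optional[int], str]]]:
    """Parse ms-style ``-T`` (optionally ``-r``) tree output.

    Returns one list per sample; entries are ``(n_sites, newick)`` where
    ``n_sites`` is the bracketed segment length prefix (``None`` without
    recombination).  Branch-length scaling and tip relabeling are left to the
    caller — this reader exists to cross-validate against an external
    simulator, not as a data path.
    """
    samples: list[list[tuple[Optional[int], str]]] = []
    current: Optional[list[tuple[Optional[int], str]]] = None
    for line in text.splitlines():
        line = line.strip()
        if line == "//":
            current = []
            samples.append(current)
        elif line.startswith("[") and "]" in line:
            if current is None:
                current = []
                samples.append(current)
            n, rest = line[1:].split("]", 1)
            current.append((int(n), rest))
        elif line.startswith("("):
            if current is None:
                current = []
                samples.append(current)
            current.append((None, line))
    return samples


def load_config(path: Union[str, Path]) -> dict:
    """Load a JSON run configuration (keys mirror ScenarioConfig)."""
    with open(path) as fh:
        return json.load(fh)


def params_from_dict(d: dict) -> IMParams:
    return IMParams(**{k: float(v) for k, v in d.items() if k in PARAM_NAMES})
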