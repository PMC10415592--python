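"""Dated trees and posterior chronogram ensembles.

A chronogram is a rooted ultrametric tree whose node heights are absolute
ages in Ma (millions of years), tips at age 0.  Posterior samples from a
relaxed molecular clock arrive as Newick tree lists (one tree per line);
this module parses them, validates ultrametricity, applies burn-in and
thinning, and summarizes clade ages with equal-tailed credible intervals.

Tree parsing and topology are delegated to :mod:`dendropy`; ages and
clade arithmetic (MRCA, crown age, stem age) are layered on top.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TreeFormatError",
    "UltrametricityError",
    "CladeDef",
    "AgeSummary",
    "Calibration",
    "Chronogram",
    "TreeEnsemble",
    "parse_newick",
    "to_chronogram",
    "load_ensemble",
    "summarize_ages",
    "read_calibrations",
    "age_summary_frame",
]


class TreeFormatError(ValueError):
    """Malformed Newick input."""


class UltrametricityError(ValueError):
    """Tips are not equidistant from the root within tolerance."""


@dataclass(frozen=True)
class CladeDef:
    """A named clade given by the leaf labels that span it."""

    name: str
    taxa: frozenset[str]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError(f"clade {self.name!r} has an empty taxon set")

    @classmethod
    def of(cls, name: str, taxa: Iterable[str]) -> "CladeDef":
        return cls(name, frozenset(taxa))


@dataclass(frozen=True)
class AgeSummary:
    """Posterior summary of one node age (Ma)."""

    n: int
    mean: float
    median: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class Calibration:
    """A secondary age calibration, data passed through to generators.

    ``clade`` is a :class:`CladeDef` or the string ``"root"``.
    """

    clade: CladeDef | str
    mean: float
    sd: float
    min_age: float
    max_age: float

    def __post_init__(self) -> None:
        if not self.min_age < self.max_age:
            raise ValueError(
                f"calibration {self._name()}: min_age {self.min_age} must be "
                f"< max_age {self.max_age}"
            )
        if not (self.min_age <= self.mean <= self.max_age):
            raise ValueError(
                f"calibration {self._name()}: mean {self.mean} outside "
                f"[{self.min_age}, {self.max_age}]"
            )

    def _name(self) -> str:
        return self.clade if isinstance(self.clade, str) else self.clade.name


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one rooted Newick tree from a string.

    Topology, leaf labels, internal labels and branch lengths are
    preserved.  Raises :class:`TreeFormatError` (with the parser's
    position information) on malformed input.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon labels" in str(exc):
            # gene trees may carry several copies per species; keep the
            # labels as plain node labels rather than taxon concepts
            try:
                return dendropy.Tree.get(
                    data=text,
                    schema="newick",
                    rooting="force-rooted",
                    preserve_underscores=True,
                    suppress_internal_node_taxa=True,
                    suppress_leaf_node_taxa=True,
                )
            except Exception as exc2:
                raise TreeFormatError(f"malformed Newick: {exc2}") from exc2
        raise TreeFormatError(f"malformed Newick: {exc}") from exc
    return tree


class Chronogram:
    """A rooted ultrametric tree with absolute node ages (Ma).

    Samples of an ensemble produced by the synthetic generator may share
    one underlying ``dendropy.Tree`` object and differ only in their age
    maps; methods never mutate the tree.
    """

    def __init__(self, tree: dendropy.Tree, node_age: dict[dendropy.Node, float]):
        self.tree = tree
        self.node_age = node_age
        self._leaf_labels: frozenset[str] | None = None
        self._leafsets: dict[dendropy.Node, frozenset[str]] | None = None

    # -- construction ---------------------------------------------------

    @classmethod
    def from_tree(cls, tree: dendropy.Tree, tolerance: float = 1e-6) -> "Chronogram":
        return to_chronogram(tree, tolerance=tolerance)

    @classmethod
    def from_newick(cls, text: str, tolerance: float = 1e-6) -> "Chronogram":
        return to_chronogram(parse_newick(text), tolerance=tolerance)

    # -- basic structure ------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def root_age(self) -> float:
        return self.node_age[self.root]

    @property
    def leaf_labels(self) -> frozenset[str]:
        if self._leaf_labels is None:
            self._leaf_labels = frozenset(
                leaf.taxon.label for leaf in self.tree.leaf_node_iter()
            )
        return self._leaf_labels

    def _leafset(self, node: dendropy.Node) -> frozenset[str]:
        if self._leafsets is None:
            sets: dict[dendropy.Node, frozenset[str]] = {}
            for nd in self.tree.postorder_node_iter():
                if nd.is_leaf():
                    sets[nd] = frozenset({nd.taxon.label})
                else:
                    s: frozenset[str] = frozenset()
                    for ch in nd.child_nodes():
                        s = s | sets[ch]
                    sets[nd] = s
            self._leafsets = sets
        return self._leafsets[node]

    def age(self, node: dendropy.Node) -> float:
        return self.node_age[node]

    # -- clade arithmetic -----------------------------------------------

    def mrca(self, taxa: Iterable[str]) -> dendropy.Node:
        """Deepest node whose subtree contains all of ``taxa``."""
        want = frozenset(taxa)
        if not want:
            raise ValueError("mrca requires a non-empty taxon set")
        missing = want - self.leaf_labels
        if missing:
            raise KeyError(f"unknown leaf label(s): {sorted(missing)}")
        # walk up from one member leaf until the subtree spans the set
        label = next(iter(want))
        node = next(
            leaf
            for leaf in self.tree.leaf_node_iter()
            if leaf.taxon.label == label
        )
        while not want <= self._leafset(node):
            node = node.parent_node
        return node

    def crown_age(self, clade: CladeDef | Iterable[str]) -> float:
        taxa = clade.taxa if isinstance(clade, CladeDef) else frozenset(clade)
        return self.node_age[self.mrca(taxa)]

    def stem_age(self, clade: CladeDef | Iterable[str]) -> float:
        """Age of the parent of the clade's MRCA; root age if the MRCA is the root."""
        taxa = clade.taxa if isinstance(clade, CladeDef) else frozenset(clade)
        node = self.mrca(taxa)
        if node.parent_node is None:
            return self.root_age
        return self.node_age[node.parent_node]

    def is_monophyletic(self, clade: CladeDef | Iterable[str]) -> bool:
        taxa = clade.taxa if isinstance(clade, CladeDef) else frozenset(clade)
        return self._leafset(self.mrca(taxa)) == taxa

    # -- output ----------------------------------------------------------

    def as_newick(self) -> str:
        """Newick string with branch lengths recomputed from node ages."""
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                nd.edge.length = None
            else:
                nd.edge.length = self.node_age[nd.parent_node] - self.node_age[nd]
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def to_chronogram(tree: dendropy.Tree, tolerance: float = 1e-6) -> Chronogram:
    """Validate ultrametricity and attach node ages.

    Node age = tree height minus root-to-node distance.  Fails with
    :class:`UltrametricityError` (naming the worst tip pair) unless all
    tips are equidistant from the root within ``tolerance`` x height.
    Tip ages are snapped to exactly 0 afterwards; all taxa are treated
    as extant.
    """
    depth: dict[dendropy.Node, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[nd] = 0.0
        else:
            length = nd.edge.length
            if length is None:
                raise TreeFormatError(
                    f"missing branch length above node "
                    f"{nd.taxon.label if nd.taxon else '<internal>'}"
                )
            if length < 0:
                raise TreeFormatError(f"negative branch length {length}")
            depth[nd] = depth[nd.parent_node] + length
    leaves = [nd for nd in tree.leaf_node_iter()]
    if not leaves:
        raise TreeFormatError("tree has no leaves")
    labels = [lf.taxon.label if lf.taxon else "?" for lf in leaves]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeFormatError(f"duplicate leaf label(s): {dup}")
    depths = [depth[lf] for lf in leaves]
    height = max(depths)
    tol = tolerance * height if height > 0 else tolerance
    lo, hi = min(depths), max(depths)
    if hi - lo > tol:
        worst_lo = labels[depths.index(lo)]
        worst_hi = labels[depths.index(hi)]
        raise UltrametricityError(
            f"tree is not ultrametric: tips {worst_lo!r} (depth {lo:g}) and "
            f"{worst_hi!r} (depth {hi:g}) differ by more than "
            f"tolerance {tol:g}"
        )
    ages = {nd: height - d for nd, d in depth.items()}
    for lf in leaves:
        ages[lf] = 0.0
    return Chronogram(tree, ages)


@dataclass
class TreeEnsemble:
    """An ordered posterior sample of chronograms sharing one leaf set."""

    samples: list[Chronogram]
    label: str = ""

    def __post_init__(self) -> None:
        if self.samples:
            ref = self.samples[0].leaf_labels
            for i, ch in enumerate(self.samples):
                if ch.leaf_labels != ref:
                    extra = sorted(ch.leaf_labels - ref)
                    missing = sorted(ref - ch.leaf_labels)
                    raise ValueError(
                        f"sample {i} leaf set differs from sample 0: "
                        f"extra={extra} missing={missing}"
                    )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def leaf_labels(self) -> frozenset[str]:
        if not self.samples:
            return frozenset()
        return self.samples[0].leaf_labels


def _read_tree_lines(path: Path) -> list[str]:
    lines = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line:
                lines.append(line)
    return lines


def apply_burnin_thin(n: int, burn_in: float, thin: int) -> list[int]:
    """Indices retained from a chain of ``n`` trees.

    The first ``floor(burn_in * n)`` samples are discarded, then every
    ``thin``-th of the remainder is kept (starting with the first).
    """
    if not 0 <= burn_in < 1:
        raise ValueError(f"burn_in must be in [0, 1), got {burn_in}")
    if thin < 1:
        raise ValueError(f"thin must be a positive count, got {thin}")
    start = math.floor(burn_in * n)
    return list(range(start, n, thin))


def load_ensemble(
    paths: Sequence[str | Path],
    burn_in: float = 0.25,
    thin: int = 1,
    label: str = "",
    tolerance: float = 1e-6,
) -> TreeEnsemble:
    """Load posterior chronograms from Newick tree-list files.

    Each file is one chain, one tree per line.  Burn-in and thinning are
    applied per file, then chains are concatenated in the order given
    (multiple chains merged after burn-in).  Leaf-set identity across all
    retained samples is enforced.

    The default ``burn_in`` of 0.25 follows the sampling scheme quoted for
    the figures; 0.20 (the Methods value) is available by argument — the
    two values are both in circulation, so this is a parameter, never
    hard-coded.
    """
    samples: list[Chronogram] = []
    for path in paths:
        lines = _read_tree_lines(Path(path))
        keep = apply_burnin_thin(len(lines), burn_in, thin)
        for i in keep:
            try:
                samples.append(Chronogram.from_newick(lines[i], tolerance=tolerance))
            except (TreeFormatError, UltrametricityError) as exc:
                raise type(exc)(f"{path}, tree {i + 1}: {exc}") from exc
    return TreeEnsemble(samples, label=label)


def summarize_ages(
    ensemble: TreeEnsemble,
    clade: CladeDef,
    mode: str = "crown",
) -> AgeSummary:
    """Mean, median and equal-tailed 95% credible interval of a clade age.

    ``mode`` selects the crown (MRCA) or stem (parent-of-MRCA) node.  The
    interval is the 2.5th-97.5th percentile range with linear
    interpolation between order statistics; highest-posterior-density
    intervals are deliberately not used (they require density estimation
    and the reported intervals are reproducible without one).
    """
    if len(ensemble) == 0:
        raise ValueError("cannot summarize an empty ensemble")
    if mode not in ("crown", "stem"):
        raise ValueError(f"mode must be 'crown' or 'stem', got {mode!r}")
    warned = False
    ages = np.empty(len(ensemble))
    for i, ch in enumerate(ensemble):
        if not warned and not ch.is_monophyletic(clade):
            logger.warning(
                "clade %r is not monophyletic in at least one sample; "
                "using spanning MRCA",
                clade.name,
            )
            warned = True
        ages[i] = ch.crown_age(clade) if mode == "crown" else ch.stem_age(clade)
    lo, hi = np.percentile(ages, [2.5, 97.5], method="linear")
    return AgeSummary(
        n=len(ensemble),
        mean=float(np.mean(ages)),
        median=float(np.median(ages)),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def read_calibrations(path: str | Path) -> list[Calibration]:
    """Read a calibration table.

    TSV columns: clade_name, taxa (semicolon-separated leaf labels, or
    the literal string ``root``), mean_Ma, sd_Ma, min_Ma, max_Ma.
    """
    df = pd.read_csv(path, sep="\t", dtype={"clade_name": str, "taxa": str})
    required = {"clade_name", "taxa", "mean_Ma", "sd_Ma", "min_Ma", "max_Ma"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration table {path} missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        taxa = str(row["taxa"]).strip()
        clade: CladeDef | str
        if taxa == "root":
            clade = "root"
        else:
            clade = CladeDef.of(str(row["clade_name"]), taxa.split(";"))
        out.append(
            Calibration(
                clade=clade,
                mean=float(row["mean_Ma"]),
                sd=float(row["sd_Ma"]),
                min_age=float(row["min_Ma"]),
                max_age=float(row["max_Ma"]),
            )
        )
    return out


def age_summary_frame(
    rows: Iterable[tuple[str, str, str, AgeSummary]],
) -> pd.DataFrame:
    """Assemble (label, clade, mode, summary) rows into the output table."""
    records = [
        {
            "label": label,
            "clade": clade,
            "mode": mode,
            "n": s.n,
            "mean": s.mean,
            "median": s.median,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
        }
        for label, clade, mode, s in rows
    ]
    return pd.DataFrame.from_records(
        records,
        columns=["label", "clade", "mode", "n", "mean", "median", "ci_low", "ci_high"],
    )
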