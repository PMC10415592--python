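"""HGT-based temporal assessment of chronogram ensembles.

A horizontal gene transfer is only chronologically possible if the donor
lineage predates the recipient.  Given a set of HGT constraints (donor
clade, recipient clade, and which node's age represents each side), each
posterior chronogram either satisfies a constraint (donor node strictly
older) or not.  The fraction of compatible samples scores how well a
clock model's posterior agrees with the transfers implied by gene/species
tree reconciliation; models are ranked by that score, and age posteriors
can be re-summarized over the compatible samples only.

Exact age ties count as incompatible: a transfer requires the donor to
strictly predate the recipient node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .trees import (
    AgeSummary,
    Chronogram,
    CladeDef,
    TreeEnsemble,
    summarize_ages,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MODES",
    "HGTConstraint",
    "CompatibilityResult",
    "is_compatible",
    "compatibility_fraction",
    "filter_compatible",
    "constrained_age_summary",
    "rank_models",
    "read_constraints",
    "constraints_frame",
    "compatibility_frame",
]

#: Which node's age represents (donor, recipient): crown = MRCA age,
#: stem = parent-of-MRCA age.
MODES = ("crown-crown", "stem-crown", "stem-stem")


@dataclass(frozen=True)
class HGTConstraint:
    """donor must be strictly older than recipient, nodes chosen per mode."""

    id: str
    donor: CladeDef
    recipient: CladeDef
    mode: str = "crown-crown"
    testable: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"constraint {self.id}: unknown mode {self.mode!r}")
        if self.testable and self.donor.taxa & self.recipient.taxa:
            raise ValueError(
                f"constraint {self.id}: donor and recipient clades overlap: "
                f"{sorted(self.donor.taxa & self.recipient.taxa)}"
            )

    def reversed(self) -> "HGTConstraint":
        """Donor and recipient swapped (same mode); used for null checks."""
        return HGTConstraint(
            id=f"{self.id}_rev",
            donor=self.recipient,
            recipient=self.donor,
            mode=self.mode,
            testable=self.testable,
        )


@dataclass(frozen=True)
class CompatibilityResult:
    label: str
    n_samples: int
    per_constraint: dict[str, float]
    joint_fraction: float
    compatible_indices: tuple[int, ...] = field(default_factory=tuple)


def _side_age(ch: Chronogram, clade: CladeDef, which: str) -> float:
    if not ch.is_monophyletic(clade):
        logger.warning(
            "clade %r not monophyletic in a sample; using spanning MRCA",
            clade.name,
        )
    return ch.crown_age(clade) if which == "crown" else ch.stem_age(clade)


def is_compatible(ch: Chronogram, constraint: HGTConstraint) -> bool:
    """True iff the donor node is strictly older than the recipient node."""
    donor_mode, recipient_mode = constraint.mode.split("-")
    donor_age = _side_age(ch, constraint.donor, donor_mode)
    recipient_age = _side_age(ch, constraint.recipient, recipient_mode)
    return donor_age > recipient_age


def compatibility_fraction(
    ensemble: TreeEnsemble, constraints: Sequence[HGTConstraint]
) -> CompatibilityResult:
    """Per-constraint and joint compatible fractions over an ensemble.

    The joint fraction uses the conjunction of all constraints per
    sample; both are always reported because the headline percentages
    may be read either way.
    """
    if len(ensemble) == 0:
        raise ValueError("cannot assess an empty ensemble")
    if not constraints:
        raise ValueError("no constraints given")
    counts = {c.id: 0 for c in constraints}
    if len(counts) != len(constraints):
        raise ValueError("constraint ids are not unique")
    compatible_indices = []
    for i, ch in enumerate(ensemble):
        ok_all = True
        for c in constraints:
            if is_compatible(ch, c):
                counts[c.id] += 1
            else:
                ok_all = False
        if ok_all:
            compatible_indices.append(i)
    n = len(ensemble)
    return CompatibilityResult(
        label=ensemble.label,
        n_samples=n,
        per_constraint={cid: k / n for cid, k in counts.items()},
        joint_fraction=len(compatible_indices) / n,
        compatible_indices=tuple(compatible_indices),
    )


def filter_compatible(
    ensemble: TreeEnsemble, constraints: Sequence[HGTConstraint]
) -> TreeEnsemble:
    """Retain exactly the samples satisfying all constraints, in order."""
    res = compatibility_fraction(ensemble, constraints)
    if not res.compatible_indices:
        raise ValueError(
            f"no sample of ensemble {ensemble.label!r} satisfies all "
            f"{len(constraints)} constraint(s); consider relaxing them"
        )
    return TreeEnsemble(
        [ensemble.samples[i] for i in res.compatible_indices],
        label=ensemble.label,
    )


def constrained_age_summary(
    ensemble: TreeEnsemble,
    constraints: Sequence[HGTConstraint],
    clade: CladeDef,
    mode: str = "crown",
) -> AgeSummary:
    """Age posterior summarized over the compatible samples only."""
    return summarize_ages(filter_compatible(ensemble, constraints), clade, mode)


def rank_models(
    ensembles: Mapping[str, TreeEnsemble],
    constraints: Sequence[HGTConstraint],
) -> list[tuple[str, float]]:
    """Rank clock models by joint compatible fraction.

    Rows are sorted by joint fraction descending, ties broken
    alphabetically by label.
    """
    if not ensembles:
        raise ValueError("no ensembles to rank")
    rows = [
        (label, compatibility_fraction(ens, constraints).joint_fraction)
        for label, ens in ensembles.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


# ---------------------------------------------------------------------------
# tables


def read_constraints(path: str | Path) -> list[HGTConstraint]:
    """Read a constraint TSV.

    Columns: constraint_id, donor_taxa (semicolon-separated leaf
    labels), recipient_taxa, mode.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"constraint_id", "donor_taxa", "recipient_taxa", "mode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"constraint table {path} missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        cid = str(row["constraint_id"])
        out.append(
            HGTConstraint(
                id=cid,
                donor=CladeDef.of(f"{cid}_donor", str(row["donor_taxa"]).split(";")),
                recipient=CladeDef.of(
                    f"{cid}_recipient", str(row["recipient_taxa"]).split(";")
                ),
                mode=str(row["mode"]),
            )
        )
    return out


def constraints_frame(constraints: Iterable[HGTConstraint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "constraint_id": c.id,
                "donor_taxa": ";".join(sorted(c.donor.taxa)),
                "recipient_taxa": ";".join(sorted(c.recipient.taxa)),
                "mode": c.mode,
            }
            for c in constraints
        ]
    )


def compatibility_frame(results: Iterable[CompatibilityResult]) -> pd.DataFrame:
    """Long-format table: label, n_samples, constraint_id, fraction, joint_fraction."""
    records = []
    for res in results:
        for cid, frac in res.per_constraint.items():
            records.append(
                {
                    "label": res.label,
                    "n_samples": res.n_samples,
                    "constraint_id": cid,
                    "fraction": frac,
                    "joint_fraction": res.joint_fraction,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["label", "n_samples", "constraint_id", "fraction", "joint_fraction"],
    )
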