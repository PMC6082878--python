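"""Group/role assignments (P1, P2, P3, outgroup) and ecological trait tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError

ROLES = ("P1", "P2", "P3", "O")
TRAITS = ("diet", "habitat", "breeding", "dimorphism")


@dataclass
class GroupAssignment:
    """Maps the four D-test roles to taxon sets, plus optional trait states.

    The four role sets must be pairwise disjoint and nonempty: a taxon cannot
    serve simultaneously as, say, P2 and outgroup in one hypothesis.
    """

    roles: dict[str, set[str]]
    traits: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if not self.roles.get(r)]
        if missing:
            raise ConfigurationError(f"empty role set(s): {missing}")
        seen: set[str] = set()
        for r in ROLES:
            overlap = seen & self.roles[r]
            if overlap:
                raise ConfigurationError(
                    f"taxa assigned to more than one role: {sorted(overlap)}"
                )
            seen |= self.roles[r]

    @property
    def p1(self) -> set[str]:
        return self.roles["P1"]

    @property
    def p2(self) -> set[str]:
        return self.roles["P2"]

    @property
    def p3(self) -> set[str]:
        return self.roles["P3"]

    @property
    def outgroup(self) -> set[str]:
        return self.roles["O"]

    def all_taxa(self) -> set[str]:
        return set().union(*(self.roles[r] for r in ROLES))

    def swap_p1_p2(self) -> "GroupAssignment":
        roles = dict(self.roles)
        roles["P1"], roles["P2"] = self.roles["P2"], self.roles["P1"]
        return GroupAssignment(roles, self.traits)


def read_group_table(path) -> GroupAssignment:
    """Parse the tab-separated assignment table.

    Columns: ``individual``, ``role`` (P1/P2/P3/O, empty = unassigned) and
    optionally the trait columns diet/habitat/breeding/dimorphism (empty =
    unknown state).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "individual" not in df.columns or "role" not in df.columns:
        raise ConfigurationError("group table needs 'individual' and 'role' columns")
    roles: dict[str, set[str]] = {r: set() for r in ROLES}
    for _, row in df.iterrows():
        role = row["role"].strip()
        if not role:
            continue
        if role not in ROLES:
            raise ConfigurationError(f"unknown role {role!r} for {row['individual']}")
        roles[role].add(row["individual"])
    trait_cols = [c for c in TRAITS if c in df.columns]
    traits = df.set_index("individual")[trait_cols] if trait_cols else None
    return GroupAssignment(roles, traits)


@dataclass
class HybridizationHypothesis:
    """A labelled gene-flow hypothesis: which lineages play P1/P2/P3/O."""

    label: str
    groups: GroupAssignment
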