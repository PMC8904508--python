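"""Y-chromosome haplogroup assignment from branch-defining markers.

A marker tree (supplied by the user, e.g. derived from the ISOGG tree)
lists, per branch, the sites whose derived state defines the branch. Reads
passing the same quality gates as genotype calling are tallied as ancestral
or derived per branch; the call is the deepest branch whose entire
root-to-branch path shows majority-derived support, with derived support
off that path flagged as conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["MarkerTree", "BranchSupport", "score_branches", "assign_haplogroup"]

TRANSITION_PAIRS = {frozenset("CT"), frozenset("GA")}


@dataclass
class Marker:
    chromosome: str
    position: int
    ancestral: str
    derived: str

    @property
    def is_transition(self) -> bool:
        return frozenset((self.ancestral, self.derived)) in TRANSITION_PAIRS


@dataclass
class MarkerTree:
    """Rooted branch tree with defining markers per branch."""

    parents: dict[str, str | None]  # branch -> parent (None at root)
    markers: dict[str, list[Marker]] = field(default_factory=dict)

    def __post_init__(self):
        roots = [b for b, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"expected one root branch, found {roots}")
        self._root = roots[0]
        for b, p in self.parents.items():
            seen = {b}
            while p is not None:
                if p in seen:
                    raise ValueError(f"cycle through branch {b!r}")
                seen.add(p)
                p = self.parents.get(p)
        sites = [
            (m.chromosome, m.position)
            for ms in self.markers.values()
            for m in ms
        ]
        if len(sites) != len(set(sites)):
            raise ValueError("marker sites must be unique across branches")

    @property
    def root(self) -> str:
        return self._root

    def children(self, branch: str) -> list[str]:
        return sorted(b for b, p in self.parents.items() if p == branch)

    def path_to(self, branch: str) -> list[str]:
        path = [branch]
        while self.parents[path[-1]] is not None:
            path.append(self.parents[path[-1]])
        return path[::-1]

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "MarkerTree":
        """Build from rows (branch, parent, chromosome, position, ancestral,
        derived); parent empty/NaN marks the root. A branch may span
        several rows, one per marker."""
        parents: dict[str, str | None] = {}
        markers: dict[str, list[Marker]] = {}
        for _, r in df.iterrows():
            b = str(r["branch"])
            p = r.get("parent")
            p = None if (pd.isna(p) or str(p) in ("", "-")) else str(p)
            if b in parents and parents[b] != p:
                raise ValueError(f"branch {b!r} listed with two parents")
            parents[b] = p
            if not pd.isna(r.get("position")):
                markers.setdefault(b, []).append(
                    Marker(
                        str(r.get("chromosome", "Y")), int(r["position"]),
                        str(r["ancestral"]).upper(), str(r["derived"]).upper(),
                    )
                )
        return cls(parents, markers)


@dataclass
class BranchSupport:
    branch: str
    derived: int
    ancestral: int
    markers_covered: int

    @property
    def supported(self) -> bool:
        """Majority rule: more derived than ancestral reads, >= 1 marker."""
        return self.markers_covered >= 1 and self.derived > self.ancestral


def score_branches(
    pileup: pd.DataFrame,
    tree: MarkerTree,
    min_base_quality: int = 30,
    min_map_quality: int = 30,
    end_trim: int = 5,
    transversions_only: bool = False,
) -> dict[str, BranchSupport]:
    """Derived/ancestral read counts per branch under the calling gates.

    ``transversions_only`` ignores C/T and G/A markers entirely, removing
    the states terminal deamination can mimic.
    """
    good = pileup[
        (pileup["base_quality"] >= min_base_quality)
        & (pileup["mapping_quality"] >= min_map_quality)
        & (pileup["read_position"] > end_trim)
        & (pileup["read_position"] <= pileup["read_length"] - end_trim)
    ]
    by_site: dict[tuple[str, int], pd.DataFrame] = {
        (str(c), int(p)): grp
        for (c, p), grp in good.groupby(["chromosome", "position"])
    }
    out = {}
    for branch in tree.parents:
        der = anc = covered = 0
        for m in tree.markers.get(branch, []):
            if transversions_only and m.is_transition:
                continue
            grp = by_site.get((m.chromosome, m.position))
            if grp is None:
                continue
            d = int((grp["base"] == m.derived).sum())
            a = int((grp["base"] == m.ancestral).sum())
            if d + a > 0:
                covered += 1
            der += d
            anc += a
        out[branch] = BranchSupport(branch, der, anc, covered)
    return out


def assign_haplogroup(
    support: dict[str, BranchSupport], tree: MarkerTree
) -> tuple[str, list[str]]:
    """Deepest branch whose whole root-to-branch path is supported.

    Branches off the called path that nonetheless show derived support are
    returned as conflicts; derived support on two sibling branches stops the
    call at their parent with both flagged. With no supported path the call
    is ``"unresolved"``.
    """
    def is_supported(branch) -> bool:
        return support.get(branch, BranchSupport(branch, 0, 0, 0)).supported

    def descend(branch) -> str:
        supported_children = [
            c for c in tree.children(branch) if is_supported(c)
        ]
        if len(supported_children) == 1:
            return descend(supported_children[0])
        return branch  # leaf, dead end, or incompatible siblings

    if is_supported(tree.root):
        call_name = descend(tree.root)
        path = tree.path_to(call_name)
    else:
        call_name = "unresolved"
        path = []
    conflicts = sorted(
        b for b, s in support.items() if s.supported and b not in path
    )
    return call_name, conflicts
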