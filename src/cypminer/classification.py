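"""Nomenclature assignment by nearest-reference identity.

Curated proteins are compared against a reference panel with the standard
CYP450 tier cutoffs — 40% amino-acid identity for family, 55% for
subfamily and 97% for allelic variants — and receive deterministic
provisional names: variants inherit the reference name with a ``v<n>``
suffix, subfamily members take the next free member number, new
subfamilies take the next free letter.  Queries below 40% to every
reference are discarded as contamination.  Boundary semantics are ``>=``
at every cutoff.  A-type means (and only means) membership of the CYP71
clan.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from ._align import pairwise_identity
from .synthetic_data import ReferencePanel

logger = logging.getLogger(__name__)

RANK_VARIANT = "allelic_variant"
RANK_SUBFAMILY = "same_subfamily"
RANK_FAMILY = "same_family"
RANK_UNRELATED = "unrelated"

DISCARD_REASON = "contamination/non-plant (identity < family cutoff)"


@dataclass(frozen=True)
class ClassificationThresholds:
    variant_min: float = 0.97
    subfamily_min: float = 0.55
    family_min: float = 0.40

    def __post_init__(self):
        if not self.family_min < self.subfamily_min < self.variant_min:
            raise ValueError("cutoffs must satisfy family < subfamily < variant")


@dataclass(frozen=True)
class ClassifiedGene:
    gene_id: str
    assigned_name: str
    family: str
    subfamily: str | None
    clan: str
    cyp_type: str            # "A" | "non-A"
    status: str              # full | partial | flagged
    nearest_ref: str
    identity: float
    rank: str
    provisional: bool = False
    variant_of: str | None = None


_NAME_RE = re.compile(r"^CYP(?P<family>\d+)(?P<subfamily>[A-Z]+)"
                      r"(?P<member>\d+)(?:v(?P<variant>\d+))?$")


def parse_cyp_name(name: str):
    """Split e.g. 'CYP76AH1' into (family='CYP76', subfamily='CYP76AH', 1)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a CYP-style name: {name!r}")
    family = f"CYP{m.group('family')}"
    return family, family + m.group("subfamily"), int(m.group("member"))


def _letters(index: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA ... (subfamily letter sequence)."""
    out = ""
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


class NameRegistry:
    """Issued-name bookkeeping; collisions raise, never renumber silently."""

    def __init__(self, panel: ReferencePanel | None = None):
        self.names: set[str] = set()
        self.members: dict[str, set[int]] = {}      # subfamily -> numbers
        self.subfamilies: dict[str, set[str]] = {}  # family -> letter suffixes
        self.variant_counts: dict[str, int] = {}    # base name -> last index
        self._provisional_counts: dict[str, int] = {}
        if panel is not None:
            for entry in panel.entries:
                self.register(entry.name)

    def register(self, name: str) -> None:
        if name in self.names:
            raise ValueError(f"registry collision on {name!r}")
        family, subfamily, member = parse_cyp_name(name)
        self.names.add(name)
        self.members.setdefault(subfamily, set()).add(member)
        self.subfamilies.setdefault(family, set()).add(subfamily[len(family):])

    def next_member(self, subfamily: str) -> int:
        used = self.members.get(subfamily, set())
        n = 1
        while n in used:
            n += 1
        return n

    def next_subfamily(self, family: str) -> str:
        used = self.subfamilies.get(family, set())
        i = 0
        while _letters(i) in used:
            i += 1
        return family + _letters(i)

    def next_variant(self, base: str) -> str:
        idx = self.variant_counts.get(base, 1) + 1
        self.variant_counts[base] = idx
        name = f"{base}v{idx}"
        if name in self.names:
            raise ValueError(f"registry collision on {name!r}")
        self.names.add(name)
        return name

    def next_provisional(self, base: str) -> str:
        idx = self._provisional_counts.get(base, 0) + 1
        self._provisional_counts[base] = idx
        return f"{base}-like-{idx}"


def nearest_reference(query: str, panel: ReferencePanel) -> tuple[str, float]:
    """Panel entry with the highest identity to the query.

    Ties go to the longer reference, then the lexicographically first
    name; tie events are logged.
    """
    if not panel.entries:
        raise ValueError("panel must be nonempty")
    scored = [(pairwise_identity(query, e.protein), e) for e in panel.entries]
    top = max(ident for ident, _ in scored)
    ties = [e for ident, e in scored if ident == top]
    longest = max(len(e.protein) for e in ties)
    winner = min((e for e in ties if len(e.protein) == longest),
                 key=lambda e: e.name)
    if len(ties) > 1:
        logger.info("nearest-reference tie at identity %.4f between %s; "
                    "kept %s", top, [e.name for e in ties], winner.name)
    return winner.name, top


def assign_rank(identity: float,
                thresholds: ClassificationThresholds | None = None) -> str:
    """Map an identity fraction to its nomenclature tier (>= semantics)."""
    th = thresholds or ClassificationThresholds()
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be in [0, 1]")
    if identity >= th.variant_min:
        return RANK_VARIANT
    if identity >= th.subfamily_min:
        return RANK_SUBFAMILY
    if identity >= th.family_min:
        return RANK_FAMILY
    return RANK_UNRELATED


def assign_name(gene_id: str, query: str, panel: ReferencePanel,
                registry: NameRegistry,
                thresholds: ClassificationThresholds | None = None,
                status: str = "full",
                clan_map: dict[str, str] | None = None) -> ClassifiedGene:
    """Classify one protein and issue its provisional name.

    Partial and flagged proteins are classified but never consume a new
    member number or subfamily letter; they attach at the best supported
    rank under a provisional ``-like-`` name.
    """
    th = thresholds or ClassificationThresholds()
    clan_map = clan_map or panel.clan_map()
    ref_name, identity = nearest_reference(query, panel)
    rank = assign_rank(identity, th)
    if rank == RANK_UNRELATED:
        raise ValueError(f"{gene_id}: {DISCARD_REASON} "
                         f"(best {identity:.3f} to {ref_name})")
    ref_family, ref_subfamily, _ = parse_cyp_name(ref_name)
    clan = clan_map[ref_family]
    cyp_type = "A" if clan == "71" else "non-A"
    provisional = status != "full"
    variant_of = None

    if rank == RANK_VARIANT:
        variant_of = ref_name
        name = (registry.next_variant(ref_name) if not provisional
                else registry.next_provisional(ref_name))
        subfamily = ref_subfamily
    elif rank == RANK_SUBFAMILY:
        subfamily = ref_subfamily
        if provisional:
            name = registry.next_provisional(subfamily)
        else:
            name = f"{subfamily}{registry.next_member(subfamily)}"
            registry.register(name)
    else:  # same family, new subfamily
        if provisional:
            subfamily = None
            name = registry.next_provisional(ref_family)
        else:
            subfamily = registry.next_subfamily(ref_family)
            name = f"{subfamily}1"
            registry.register(name)

    return ClassifiedGene(gene_id=gene_id, assigned_name=name,
                          family=ref_family, subfamily=subfamily, clan=clan,
                          cyp_type=cyp_type, status=status,
                          nearest_ref=ref_name, identity=identity, rank=rank,
                          provisional=provisional, variant_of=variant_of)


def classify_all(proteins: dict[str, tuple[str, str]], panel: ReferencePanel,
                 thresholds: ClassificationThresholds | None = None
                 ) -> tuple[list[ClassifiedGene], list[tuple[str, float, str]]]:
    """Classify {gene_id: (protein, status)}; returns (classified, discarded).

    Discarded entries carry (gene_id, best identity, reason).
    """
    th = thresholds or ClassificationThresholds()
    registry = NameRegistry(panel)
    classified, discarded = [], []
    for gene_id in sorted(proteins):
        protein, status = proteins[gene_id]
        ref_name, identity = nearest_reference(protein, panel)
        if assign_rank(identity, th) == RANK_UNRELATED:
            discarded.append((gene_id, identity, DISCARD_REASON))
            continue
        classified.append(assign_name(gene_id, protein, panel, registry, th,
                                      status=status))
    return classified, discarded
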