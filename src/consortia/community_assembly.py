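"""Merge namespaced sub-models into one community model.

Inter-strain flow passes exclusively through a shared extracellular pool.
For a community inoculated at fractions m_A : m_B : ... (normalized to sum
to 1), each strain's copy of a shared metabolite is connected to the pool by
a pair of irreversible link reactions

    1.0 meta_e@A  ->  (1/m_A) meta_shared      (forward)
    (1/m_A) meta_shared  ->  1.0 meta_e@A      (reverse)

so that at steady state the link fluxes of two strains across one shared
metabolite stand in the ratio m_A : m_B.  This is the modular interaction
scale constraint: the inoculation ratio enters the stoichiometric matrix
itself, and a ratio sweep only rescales link coefficients, never the
sub-models.

Links are created only for metabolites explicitly listed as shared (the
curated cross-feeding design), not for every extracellular metabolite.
No combined community biomass reaction is created; growth appears only
through per-strain biomass reactions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import AssemblyError
from .gem_io import (
    KIND_EXCHANGE,
    KIND_LINK,
    REVERSE_SUFFIX,
    Metabolite,
    ReactionIR,
    StrainModel,
)

__all__ = [
    "RatioSpec",
    "InteractionLink",
    "CommunityModel",
    "namespace",
    "assemble",
    "add_shared_exchange",
    "set_substrate_ratio",
    "set_ratio",
    "shared_metabolite_id",
]

logger = logging.getLogger(__name__)

NAMESPACE_SEP = "@"
SHARED = "shared"


@dataclass(frozen=True)
class RatioSpec:
    """Inoculation fractions per strain tag, e.g. {"A": 2, "B": 1}.

    Raw integer ratios are accepted; :meth:`normalize` rescales them to sum
    to 1 so that objective values are comparable across sweeps.  A zero
    fraction is not allowed — drop the strain (omit its links) instead.
    """

    fractions: tuple[tuple[str, float], ...]
    normalized: bool = False

    @classmethod
    def of(cls, fractions: Mapping[str, float] | Sequence[tuple[str, float]]) -> "RatioSpec":
        items = tuple(fractions.items()) if isinstance(fractions, Mapping) else tuple(fractions)
        spec = cls(fractions=tuple((str(t), float(v)) for t, v in items))
        spec._check()
        return spec

    @classmethod
    def from_string(cls, text: str, tags: Sequence[str]) -> "RatioSpec":
        """Parse "2:1" / "2:3:1" against an ordered tag list."""
        parts = [float(p) for p in text.split(":")]
        if len(parts) != len(tags):
            raise AssemblyError(
                f"ratio {text!r} has {len(parts)} terms for {len(tags)} strains"
            )
        return cls.of(list(zip(tags, parts)))

    def _check(self) -> None:
        for tag, frac in self.fractions:
            if not frac > 0:
                raise AssemblyError(
                    f"fraction for strain {tag!r} must be > 0 (got {frac}); "
                    "express absence by omitting the strain's links"
                )

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.fractions)

    def as_dict(self) -> dict[str, float]:
        return dict(self.fractions)

    def normalize(self) -> "RatioSpec":
        total = sum(v for _, v in self.fractions)
        return RatioSpec(
            fractions=tuple((t, v / total) for t, v in self.fractions),
            normalized=True,
        )

    def label(self) -> str:
        return ":".join(f"{v:g}" for _, v in self.fractions)


@dataclass
class InteractionLink:
    """Bookkeeping for one (shared metabolite, strain) link pair."""

    base_metabolite: str
    strain: str
    strain_metabolite: str
    shared_metabolite: str
    forward_id: str
    reverse_id: str
    scale_coefficient: float  # 1 / m_strain


@dataclass
class CommunityModel:
    submodels: list[StrainModel] = field(default_factory=list)
    shared_metabolites: dict[str, Metabolite] = field(default_factory=dict)
    links: list[InteractionLink] = field(default_factory=list)
    link_reactions: dict[str, ReactionIR] = field(default_factory=dict)
    shared_exchanges: dict[str, ReactionIR] = field(default_factory=dict)
    ratio: Optional[RatioSpec] = None
    objective: Optional[str] = None

    @property
    def strain_tags(self) -> tuple[str, ...]:
        return tuple(m.tag for m in self.submodels)

    def submodel(self, tag: str) -> StrainModel:
        for m in self.submodels:
            if m.tag == tag:
                return m
        raise KeyError(f"no sub-model tagged {tag!r}")

    def all_reactions(self) -> Iterable[ReactionIR]:
        for sub in self.submodels:
            yield from sub.reactions.values()
        yield from self.link_reactions.values()
        yield from self.shared_exchanges.values()

    def all_metabolites(self) -> dict[str, Metabolite]:
        out: dict[str, Metabolite] = {}
        for sub in self.submodels:
            out.update(sub.metabolites)
        out.update(self.shared_metabolites)
        return out

    def get_reaction(self, rid: str) -> ReactionIR:
        for sub in self.submodels:
            if rid in sub.reactions:
                return sub.reactions[rid]
        if rid in self.link_reactions:
            return self.link_reactions[rid]
        if rid in self.shared_exchanges:
            return self.shared_exchanges[rid]
        raise KeyError(f"no reaction {rid!r} in community")

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            submodels=[m.copy() for m in self.submodels],
            shared_metabolites={k: replace(v) for k, v in self.shared_metabolites.items()},
            links=[replace(l) for l in self.links],
            link_reactions={k: r.copy() for k, r in self.link_reactions.items()},
            shared_exchanges={k: r.copy() for k, r in self.shared_exchanges.items()},
            ratio=self.ratio,
            objective=self.objective,
        )

    def validate(self) -> None:
        mets = self.all_metabolites()
        touched: set[str] = set()
        for rxn in self.all_reactions():
            origins = set()
            for mid in rxn.stoichiometry:
                if mid not in mets:
                    raise AssemblyError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
                if mid in self.shared_metabolites:
                    touched.add(mid)
                else:
                    origins.add(mets[mid].origin)
            if len(origins) > 1:
                raise AssemblyError(
                    f"reaction {rxn.id!r} connects strain namespaces {sorted(origins)} "
                    "directly; inter-strain flow must pass through shared metabolites"
                )
        untouched = set(self.shared_metabolites) - touched
        if untouched:
            raise AssemblyError(
                "shared metabolite(s) touched by no link or exchange: "
                + ", ".join(sorted(untouched))
            )


# ---------------------------------------------------------------------------


def namespace(model: StrainModel, tag: str, sep: str = NAMESPACE_SEP) -> StrainModel:
    """Suffix every metabolite and reaction id with the strain tag.

    ``glc__D_e`` tagged "A" becomes ``glc__D_e@A`` with base_id
    ``glc__D_e``.  Namespacing an already-tagged model is refused.
    """
    if not tag:
        raise AssemblyError("strain tag must be nonempty")
    if model.tag:
        raise AssemblyError(
            f"model already namespaced with tag {model.tag!r}; refusing to re-tag"
        )
    suffix = sep + tag
    out = StrainModel(tag=tag, biomass_id=None, pool=model.pool)
    for met in model.metabolites.values():
        out.metabolites[met.id + suffix] = replace(
            met, id=met.id + suffix, base_id=met.base_id, origin=tag
        )
    for rxn in model.reactions.values():
        new = rxn.copy()
        new.id = rxn.id + suffix
        new.base_id = rxn.base_id
        new.origin = tag
        new.stoichiometry = {m + suffix: c for m, c in rxn.stoichiometry.items()}
        out.reactions[new.id] = new
    if model.biomass_id is not None:
        out.biomass_id = model.biomass_id + suffix
    if out.pool is not None and getattr(out.pool, "tag", tag) not in ("", tag):
        raise AssemblyError(
            f"enzyme pool tagged {out.pool.tag!r} attached to strain {tag!r}"
        )
    return out


def shared_metabolite_id(base_id: str) -> str:
    """Shared-pool id for an extracellular base id: glc__D_e -> glc__D_shared."""
    stem = base_id[:-2] if base_id.endswith("_e") else base_id
    return stem + "_" + SHARED


def _link_ids(base_id: str, tag: str, sep: str) -> tuple[str, str]:
    fwd = f"LINK_{base_id}{sep}{tag}"
    return fwd, fwd + REVERSE_SUFFIX


def _make_link_pair(
    base_id: str, tag: str, strain_met: str, shared_met: str, coeff: float, sep: str
) -> tuple[InteractionLink, ReactionIR, ReactionIR]:
    fwd_id, rev_id = _link_ids(base_id, tag, sep)
    fwd = ReactionIR(
        id=fwd_id,
        stoichiometry={strain_met: -1.0, shared_met: coeff},
        upper_bound=math.inf,
        origin=tag,
        kind=KIND_LINK,
    )
    rev = ReactionIR(
        id=rev_id,
        stoichiometry={strain_met: 1.0, shared_met: -coeff},
        upper_bound=math.inf,
        origin=tag,
        kind=KIND_LINK,
        base_id=fwd_id + REVERSE_SUFFIX,
    )
    link = InteractionLink(
        base_metabolite=base_id,
        strain=tag,
        strain_metabolite=strain_met,
        shared_metabolite=shared_met,
        forward_id=fwd_id,
        reverse_id=rev_id,
        scale_coefficient=coeff,
    )
    return link, fwd, rev


def assemble(
    submodels: Sequence[StrainModel],
    shared_ids: Sequence[str],
    ratio: RatioSpec | Mapping[str, float],
    sep: str = NAMESPACE_SEP,
) -> CommunityModel:
    """Merge namespaced, irreversibility-split sub-models into a community.

    One shared pool metabolite is created per entry of ``shared_ids`` (given
    as pre-namespace base ids); every strain that carries that extracellular
    metabolite gets a reversible link pair with shared-side coefficient
    1/m_strain.  Shared exchanges are added separately with
    :func:`add_shared_exchange`.
    """
    if not isinstance(ratio, RatioSpec):
        ratio = RatioSpec.of(ratio)
    tags = [m.tag for m in submodels]
    if len(set(tags)) != len(tags):
        raise AssemblyError(f"duplicate strain tags in assembly: {tags}")
    if any(not t for t in tags):
        raise AssemblyError("all sub-models must be namespaced before assembly")
    if set(ratio.tags) != set(tags):
        raise AssemblyError(
            f"ratio covers {ratio.tags} but sub-models are tagged {tuple(tags)}"
        )
    for sub in submodels:
        for rxn in sub.reactions.values():
            if rxn.lower_bound < 0:
                raise AssemblyError(
                    f"sub-model {sub.tag!r} is not irreversibility-split "
                    f"(reaction {rxn.id!r} has lower bound {rxn.lower_bound})"
                )
    if not ratio.normalized:
        logger.info("normalizing inoculation ratio %s", ratio.label())
        ratio = ratio.normalize()
    fractions = ratio.as_dict()

    community = CommunityModel(submodels=[m.copy() for m in submodels], ratio=ratio)
    for base_id in shared_ids:
        shared_id = shared_metabolite_id(base_id)
        carriers = []
        for sub in community.submodels:
            hits = [m for m in sub.metabolites.values() if m.base_id == base_id]
            if hits:
                carriers.append((sub.tag, hits[0].id))
        if not carriers:
            raise AssemblyError(
                f"shared metabolite {base_id!r} is absent from every sub-model"
            )
        template = community.submodel(carriers[0][0]).metabolites[carriers[0][1]]
        community.shared_metabolites[shared_id] = Metabolite(
            id=shared_id,
            base_id=base_id,
            name=template.name,
            compartment=SHARED,
            formula=template.formula,
            origin=SHARED,
        )
        for tag, strain_met in carriers:
            coeff = 1.0 / fractions[tag]
            link, fwd, rev = _make_link_pair(
                base_id, tag, strain_met, shared_id, coeff, sep
            )
            community.links.append(link)
            community.link_reactions[fwd.id] = fwd
            community.link_reactions[rev.id] = rev
    community.validate()
    return community


def add_shared_exchange(
    community: CommunityModel,
    base_id: str,
    uptake_ub: float,
    secretion_ub: float,
) -> CommunityModel:
    """Add a secretion/uptake exchange pair on a shared pool metabolite.

    The forward reaction secretes (consumes the shared metabolite); the
    ``_reverse`` sibling takes it up with upper bound ``uptake_ub``.
    """
    shared_id = shared_metabolite_id(base_id)
    out = community.copy()
    if shared_id not in out.shared_metabolites:
        raise AssemblyError(f"no shared metabolite for base id {base_id!r}")
    ex_id = "EX_" + shared_id
    if ex_id in out.shared_exchanges:
        raise AssemblyError(f"exchange {ex_id!r} already present")
    out.shared_exchanges[ex_id] = ReactionIR(
        id=ex_id,
        stoichiometry={shared_id: -1.0},
        upper_bound=float(secretion_ub),
        origin=SHARED,
        kind=KIND_EXCHANGE,
    )
    out.shared_exchanges[ex_id + REVERSE_SUFFIX] = ReactionIR(
        id=ex_id + REVERSE_SUFFIX,
        stoichiometry={shared_id: 1.0},
        upper_bound=float(uptake_ub),
        origin=SHARED,
        kind=KIND_EXCHANGE,
        base_id=ex_id + REVERSE_SUFFIX,
    )
    return out


def set_substrate_ratio(
    community: CommunityModel,
    ratios: Mapping[str, float],
    total: float,
) -> CommunityModel:
    """Rescale uptake upper bounds to a fixed weight ratio under a total cap.

    ``ratios`` maps uptake reaction ids (e.g. ``EX_glc__D_shared_reverse``)
    to positive weights; bounds become total * w_i / sum(w).  With a single
    substrate the bound is simply the cap.
    """
    out = community.copy()
    weight_sum = 0.0
    for rid, w in ratios.items():
        if not w > 0:
            raise AssemblyError(f"substrate weight for {rid!r} must be > 0, got {w}")
        out.get_reaction(rid)  # KeyError contract: must exist
        weight_sum += w
    for rid, w in ratios.items():
        out.get_reaction(rid).upper_bound = total * w / weight_sum
    return out


def set_ratio(community: CommunityModel, ratio: RatioSpec | Mapping[str, float]) -> CommunityModel:
    """Rebuild all link coefficients for a new inoculation ratio.

    Everything else in the model is untouched, so ratio sweeps never
    reassemble.  Idempotent for an unchanged ratio.
    """
    if not isinstance(ratio, RatioSpec):
        ratio = RatioSpec.of(ratio)
    missing = set(community.strain_tags) - set(ratio.tags)
    if missing:
        raise AssemblyError(f"ratio missing strain(s): {sorted(missing)}")
    if not ratio.normalized:
        ratio = ratio.normalize()
    fractions = ratio.as_dict()
    out = community.copy()
    out.ratio = ratio
    for link in out.links:
        coeff = 1.0 / fractions[link.strain]
        link.scale_coefficient = coeff
        out.link_reactions[link.forward_id].stoichiometry = {
            link.strain_metabolite: -1.0,
            link.shared_metabolite: coeff,
        }
        out.link_reactions[link.reverse_id].stoichiometry = {
            link.strain_metabolite: 1.0,
            link.shared_metabolite: -coeff,
        }
    return out
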