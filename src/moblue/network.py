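"""Coarse-grained self-assembly reaction network for molybdenum-oxide clusters.

The model tracks only nuclearity (Mo atoms per molecule) and a minimal
amount of structural identity: a single generic species per nuclearity,
except at nuclearity 2 where the corner-shared {Mo2c} and the reduced,
edge-shared {Mo2e} dimers are distinguished because they feed different
giant products (the {Mo154} wheel and the {Mo132} Keplerate ball,
respectively).  Every reaction is reversible and decomposed into elementary
steps: bimolecular synthesis ``A + B -> C`` and unimolecular degradation
``C -> A + B``.

Assembly is organised as a funnel around the {Mo36} template:

* the **oxidized condensation chain**: corner dimers condense into the
  small oligomers ({Mo2c}+{Mo2c} -> {Mo4}, {Mo4}+{Mo2c} -> {Mo6}), and the
  {Mo6} hexamer chain assembles the template ({Mo6}+{Mo6} -> {Mo12} -> ...
  -> {Mo36}).  The hexamer is a dedicated structural block: amorphous
  aggregates never absorb it.  The reduced edge dimer takes part in no
  oxidized chemistry at all;
* **giant paths**: both giants nucleate by capturing a template.  The
  wheel path starts with {Mo36}+{Mo6} (the host-guest wheel grown around
  its template) and is hexamer-fed with two corner-dimer closures; the
  ball path starts with {Mo36}+{Mo2e} and is a pure reduced-dimer ladder.
  Each path intermediate admits exactly the next addition of its canonical
  build sequence; the terminal step yields the stable giant (degradation
  constant ``k_d``);
* **amorphous aggregates** ("junk"): seeded by chance collisions of small
  oligomers, they accrete monomers (and, in the all-pairs mode used for
  small networks, merge freely) and shed fragments at a size-proportional
  rate -- an n-mer has ~n/2 ways to fall apart, so junk cycles mass
  instead of trapping it.

The dimerization ratio ``D`` (corner : edge rate constants, the model's
stand-in for pH / reduction potential) steers the {Mo154} vs {Mo132}
competition: low D starves the oxidized chain (no {Mo6}, no template and
eventually no giants at all), high D starves the reduced-dimer pool the
ball shell is built from.  The {Mo36} template accelerates the wheel path
it templates and its own assembly route -- the embedded autocatalytic
loop by which one completed template coordinates the fragments of the
next copy.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

GENERIC = "generic"
CORNER = "corner_dimer_path"
EDGE = "edge_dimer_path"

#: which path lineage feeds which giant, by nuclearity
DEFAULT_GIANT_LINEAGE = {154: CORNER, 132: EDGE}
#: path suffix per lineage used in species ids ("w"heel / "b"all)
_PATH_SUFFIX = {CORNER: "w", EDGE: "b"}
_DIMER_OF = {CORNER: "Mo2c", EDGE: "Mo2e"}

DEFAULT_TARGETS = (36, 132, 154)


class NetworkError(ValueError):
    """Invalid network construction request."""


@dataclass(frozen=True)
class Species:
    """One coarse-grained assembly species.

    ``free_sites`` is the bonding-site proxy: for a species of nuclearity n
    on the path to a giant of nuclearity N it is N - n; for generic species
    it is the distance to the network cap (floored at 1 so that zero free
    sites identifies completed targets only); targets have 0.  ``mass``
    overrides the default collision mass (nuclearity x mass_per_mo) and is
    used for the non-cluster inhibitor species.
    """

    id: str
    nuclearity: int
    lineage: str = GENERIC
    free_sites: int = 1
    is_template: bool = False
    is_target: bool = False
    mass: float | None = None
    inert: bool = False


@dataclass(frozen=True)
class Reaction:
    """A single elementary reversible-half step.

    ``plain_rate`` marks bookkeeping reactions (inhibitor binding/release)
    whose constants are used verbatim, bypassing the collision prefactor,
    templating and completion bias.
    """

    kind: str  # "synthesis" | "degradation"
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    base_k: float = 1.0
    template_id: str | None = None
    plain_rate: bool = False

    def key(self) -> tuple:
        return (self.kind, tuple(sorted(self.reactants)), tuple(sorted(self.products)))


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    max_nuclearity: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {sp.id: sp for sp in self.species}
        if len(self._index) != len(self.species):
            raise NetworkError("duplicate species ids")

    @property
    def species_by_id(self) -> Mapping[str, Species]:
        return self._index

    def species_ids(self) -> list[str]:
        return [sp.id for sp in self.species]

    def validate(self) -> list[str]:
        """Structural invariant check; returns violations (empty when clean)."""
        bad: list[str] = []
        seen: set[tuple] = set()
        forward: set[tuple] = set()
        backward: set[tuple] = set()
        for rx in self.reactions:
            for sid in (*rx.reactants, *rx.products):
                if sid not in self._index:
                    bad.append(f"{rx}: unresolved species {sid!r}")
            if any(s not in self._index for s in (*rx.reactants, *rx.products)):
                continue
            n_in = sum(self._index[s].nuclearity for s in rx.reactants)
            n_out = sum(self._index[s].nuclearity for s in rx.products)
            if n_in != n_out:
                bad.append(f"{rx}: nuclearity not conserved ({n_in} -> {n_out})")
            if rx.kind == "synthesis" and (len(rx.reactants), len(rx.products)) != (2, 1):
                bad.append(f"{rx}: synthesis must be A+B->C")
            if rx.kind == "degradation" and (len(rx.reactants), len(rx.products)) != (1, 2):
                bad.append(f"{rx}: degradation must be C->A+B")
            if rx.kind not in ("synthesis", "degradation"):
                bad.append(f"{rx}: unknown kind")
            k = rx.key()
            if k in seen:
                bad.append(f"{rx}: duplicate reaction")
            seen.add(k)
            pair = (tuple(sorted(rx.reactants)), tuple(sorted(rx.products)))
            if rx.kind == "synthesis":
                forward.add(pair)
            elif rx.kind == "degradation":
                backward.add((pair[1], pair[0]))
        if forward != backward:
            missing = forward.symmetric_difference(backward)
            bad.append(f"reversibility broken for {sorted(missing)[:5]} ...")
        return bad

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "max_nuclearity": self.max_nuclearity,
            "metadata": self.metadata,
            "species": [vars(sp) | {} for sp in self.species],
            "reactions": [
                {
                    "kind": rx.kind,
                    "reactants": list(rx.reactants),
                    "products": list(rx.products),
                    "base_k": rx.base_k,
                    "template_id": rx.template_id,
                    "plain_rate": rx.plain_rate,
                }
                for rx in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ReactionNetwork":
        species = [Species(**raw) for raw in payload["species"]]
        reactions = [
            Reaction(
                kind=raw["kind"],
                reactants=tuple(raw["reactants"]),
                products=tuple(raw["products"]),
                base_k=raw.get("base_k", 1.0),
                template_id=raw.get("template_id"),
                plain_rate=raw.get("plain_rate", False),
            )
            for raw in payload["reactions"]
        ]
        return cls(
            species,
            reactions,
            payload["max_nuclearity"],
            dict(payload.get("metadata", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_edge_dataframe(self) -> pd.DataFrame:
        """Flat edge list (one row per reactant->product edge) for graph tools."""
        rows = []
        for i, rx in enumerate(self.reactions):
            for r in rx.reactants:
                for p in rx.products:
                    rows.append(
                        {
                            "reaction": i,
                            "kind": rx.kind,
                            "source": r,
                            "target": p,
                            "base_k": rx.base_k,
                            "template_id": rx.template_id or "",
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species enumeration
# ---------------------------------------------------------------------------


def _normalize_targets(targets: Sequence[int], mixing_threshold: int) -> dict:
    """Split targets into the template target and giant path targets."""
    targets = sorted(set(int(t) for t in targets))
    if not targets:
        return {"template": None, "giants": {}}
    template = targets[0]
    giants = {}
    for t in targets[1:]:
        if t not in DEFAULT_GIANT_LINEAGE:
            raise NetworkError(
                f"no default path lineage for giant target {t}; "
                f"known giants: {sorted(DEFAULT_GIANT_LINEAGE)}"
            )
        giants[t] = DEFAULT_GIANT_LINEAGE[t]
    if giants and template <= mixing_threshold:
        raise NetworkError("path targets require a template target above the threshold")
    return {"template": template, "giants": giants}


def enumerate_species(
    max_nuclearity: int,
    targets: Sequence[int] = (),
    mixing_threshold: int = 6,
) -> list[Species]:
    """Enumerate the coarse-grained species space.

    One generic species per nuclearity 1..max (nuclearity 2 splits into the
    two dimers), plus lineage-tagged path intermediates between the template
    target and each giant.  Giant nuclearities exist only as path terminals.
    """
    if max_nuclearity < 1:
        raise NetworkError("max_nuclearity must be >= 1")
    if targets and max_nuclearity < max(targets):
        raise NetworkError(
            f"max_nuclearity {max_nuclearity} below largest target {max(targets)}"
        )
    t = _normalize_targets(targets, mixing_threshold)
    template_n, giants = t["template"], t["giants"]
    # generic aggregates have no defined completion: their open surface is
    # always large, so they carry a flat, large free-site count and gain no
    # completion bias; only path intermediates count down to their target
    fs_generic = lambda n: max_nuclearity  # noqa: E731

    corner_target = next((g for g, lin in giants.items() if lin == CORNER), None)
    edge_target = next((g for g, lin in giants.items() if lin == EDGE), None)

    out: list[Species] = [Species("Mo1", 1, GENERIC, fs_generic(1))]
    if max_nuclearity >= 2:
        out.append(
            Species(
                "Mo2c", 2, CORNER,
                corner_target - 2 if corner_target else fs_generic(2),
            )
        )
        out.append(
            Species(
                "Mo2e", 2, EDGE,
                edge_target - 2 if edge_target else fs_generic(2),
            )
        )
    giant_ns = set(giants)
    for n in range(3, max_nuclearity + 1):
        if n in giant_ns:
            continue
        if template_n is not None and n == template_n:
            out.append(Species(f"Mo{n}", n, GENERIC, 0, is_template=True, is_target=True))
        else:
            out.append(Species(f"Mo{n}", n, GENERIC, fs_generic(n)))
    for giant_n, lineage in giants.items():
        suffix = _PATH_SUFFIX[lineage]
        start = _path_start(template_n, lineage)
        # the ball shell is pure reduced dimers; the wheel is hexamer-fed
        # with two corner-dimer closures
        hexes = 0 if lineage == EDGE else (giant_n - start) // 6
        for n in _canonical_path(start, giant_n, hexes)[:-1]:
            out.append(Species(f"Mo{n}{suffix}", n, lineage, giant_n - n))
        out.append(Species(f"Mo{giant_n}", giant_n, lineage, 0, is_target=True))
    return out


def _path_start(template_n: int | None, lineage: str) -> int:
    """Entry nuclearity: the template captures {Mo6} (wheel) or {Mo2e} (ball)."""
    if template_n is None:
        raise NetworkError("giant paths require a template target")
    return template_n + (6 if lineage == CORNER else 2)


def _canonical_path(start: int, giant: int, n_hex: int | None = None) -> list[int]:
    """Nuclearities along the canonical build sequence start -> giant.

    The remaining mass is split into dimer (+2) and {Mo6} (+6) additions.
    With ``n_hex=None`` the two block types are as balanced as the
    arithmetic allows and spread evenly (the wheel's interleave of corner
    dimers and hexamers); ``n_hex=0`` gives a pure dimer ladder (the ball's
    reduced shell).  Returns the visited nuclearities including both
    endpoints; each intermediate admits exactly one next addition.
    """
    delta = giant - start
    if delta < 0 or delta % 2:
        raise NetworkError(f"no +2/+6 build sequence from {start} to {giant}")
    if n_hex is None:
        n_hex = delta // 8
    if not 0 <= 6 * n_hex <= delta:
        raise NetworkError("invalid hexamer count for build sequence")
    n_dim = (delta - 6 * n_hex) // 2
    total = n_hex + n_dim
    seq = [start]
    n = start
    done_hex = 0
    for i in range(1, total + 1):
        if round(i * n_hex / total) > done_hex:
            n += 6
            done_hex += 1
        else:
            n += 2
        seq.append(n)
    assert seq[-1] == giant
    return seq


# ---------------------------------------------------------------------------
# reaction enumeration
# ---------------------------------------------------------------------------


def _products_of(
    a: Species,
    b: Species,
    index: Mapping[str, Species],
    max_nuclearity: int,
    mixing_threshold: int,
    blocks_only: bool,
    template_n: int | None,
    giant_ns: Mapping[int, str],
    path_succ: Mapping[str, Mapping[int, int]],
) -> list[Species]:
    """Product species for an unordered reactant pair, or [] if disallowed."""
    if a.inert or b.inert or a.nuclearity == 0 or b.nuclearity == 0:
        return []
    n = a.nuclearity + b.nuclearity
    if n > max_nuclearity:
        return []

    # monomer + monomer: both dimer channels
    if a.id == "Mo1" and b.id == "Mo1":
        return [index[i] for i in ("Mo2c", "Mo2e") if i in index]

    def is_path(sp: Species) -> bool:
        return sp.lineage in (CORNER, EDGE) and sp.nuclearity > 2 and not sp.is_target

    # completed targets only react through path entry: both giants nucleate
    # around a captured template — the wheel grows from {Mo36} + {Mo6}
    # (the host-guest wheel), the reduced ball shell from {Mo36} + {Mo2e};
    # the D transition is the split of the shared template budget between
    # the hexamer and reduced-dimer pools
    if a.is_target or b.is_target:
        tpl, other = (a, b) if a.is_target else (b, a)
        if not tpl.is_template:
            return []
        lineage = {_DIMER_OF[EDGE]: EDGE, "Mo6": CORNER}.get(other.id)
        if lineage is None:
            return []
        cand = _path_id(n, lineage, giant_ns)
        return [index[cand]] if cand and cand in index else []

    # path intermediates admit exactly the next addition of their canonical
    # build sequence (their own dimer for +2 steps, {Mo6} for +6 steps)
    if is_path(a) or is_path(b):
        if is_path(a) and is_path(b):
            return []
        p, blk = (a, b) if is_path(a) else (b, a)
        succ = path_succ.get(p.lineage, {}).get(p.nuclearity)
        if succ is None or n != succ:
            return []
        need = _DIMER_OF[p.lineage] if succ - p.nuclearity == 2 else "Mo6"
        if blk.id != need:
            return []
        cand = _path_id(succ, p.lineage, giant_ns)
        return [index[cand]] if cand and cand in index else []

    # the reduced edge dimer is a structural unit of the molybdenum-blue
    # ball only: it never joins the oxidized chain or amorphous aggregates
    if "Mo2e" in (a.id, b.id):
        return []
    # the small oxidized oligomers condense from corner dimers alone
    # (2c+2c -> 4, 4+2c -> 6); monomers only feed dimerization and junk
    if "Mo1" in (a.id, b.id) and n <= mixing_threshold:
        return []
    if template_n is not None and "Mo6" in (a.id, b.id):
        # the {Mo6} hexamer is a dedicated building block of structured
        # species: the template is an assembly of hexamers (6 -> 12 -> ...
        # -> 36) and the giant paths consume {Mo6} directly, but amorphous
        # aggregates never absorb it
        if a.id != b.id:
            partner = b if a.id == "Mo6" else a
            if partner.nuclearity % 6 or partner.nuclearity > template_n - 6:
                return []
    elif blocks_only:
        # amorphous aggregates accrete monomers; they are seeded by chance
        # collisions of the small oxidized oligomers
        small = a.nuclearity <= mixing_threshold and b.nuclearity <= mixing_threshold
        if "Mo1" not in (a.id, b.id) and not small:
            return []
    if n in giant_ns:
        return []  # giants form only through their templated path
    if template_n is not None and n == template_n and "Mo6" not in (a.id, b.id):
        return []  # the template crystallizes from hexamers, never from junk
    cand = f"Mo{n}"
    if cand in index:
        return [index[cand]]
    return []


def _path_id(n: int, lineage: str, giant_ns: Mapping[int, str]) -> str | None:
    giant = next((g for g, lin in giant_ns.items() if lin == lineage), None)
    if giant is None or n > giant:
        return None
    if n == giant:
        return f"Mo{giant}"
    return f"Mo{n}{_PATH_SUFFIX[lineage]}"


def enumerate_reactions(
    species: Sequence[Species],
    max_nuclearity: int,
    growth_mode: str = "auto",
    mixing_threshold: int = 6,
) -> ReactionNetwork:
    """All reversible synthesis/degradation pairs over ``species``.

    ``growth_mode`` controls how amorphous aggregates grow: "pairs" lets
    any two compatible generic species merge (the paper-style all-pairs
    enumeration, quadratic in the cap), while "blocks" restricts them to
    monomer accretion seeded by small-oligomer collisions, keeping large
    networks tractable; "auto" picks pairs for max_nuclearity <= 40 and
    blocks above.  Structured routes (dimerization, the oxidized
    condensation chain, template capture and the giant paths) are the same
    in both modes.
    """
    if growth_mode not in ("auto", "pairs", "blocks"):
        raise NetworkError(f"unknown growth_mode {growth_mode!r}")
    blocks_only = growth_mode == "blocks" or (
        growth_mode == "auto" and max_nuclearity > 40
    )
    index = {sp.id: sp for sp in species}
    template_n = next((sp.nuclearity for sp in species if sp.is_template), None)
    giant_ns = {
        sp.nuclearity: sp.lineage
        for sp in species
        if sp.is_target and not sp.is_template
    }
    # successor map along each path's canonical build sequence
    path_succ: dict[str, dict[int, int]] = {}
    for lineage in (CORNER, EDGE):
        ns = sorted(
            sp.nuclearity
            for sp in species
            if sp.lineage == lineage and sp.nuclearity > 2 and not sp.is_target
        )
        giant = next((g for g, lin in giant_ns.items() if lin == lineage), None)
        if giant is not None:
            ns.append(giant)
        path_succ[lineage] = {a: b for a, b in zip(ns, ns[1:])}
    reactions: list[Reaction] = []
    seen: set[tuple] = set()
    for a, b in itertools.combinations_with_replacement(
        sorted(species, key=lambda s: s.id), 2
    ):
        for prod in _products_of(
            a, b, index, max_nuclearity, mixing_threshold,
            blocks_only, template_n, giant_ns, path_succ,
        ):
            fwd = Reaction("synthesis", (a.id, b.id), (prod.id,))
            if fwd.key() in seen:
                continue
            seen.add(fwd.key())
            reactions.append(fwd)
            reactions.append(Reaction("degradation", (prod.id,), (a.id, b.id)))
    net = ReactionNetwork(
        list(species),
        reactions,
        max_nuclearity,
        {
            "growth_mode": "blocks" if blocks_only else "pairs",
            "mixing_threshold": mixing_threshold,
        },
    )
    issues = net.validate()
    if issues:  # pragma: no cover - enumeration bug guard
        raise NetworkError("; ".join(issues[:3]))
    return net


# ---------------------------------------------------------------------------
# rate-constant assignment and template annotation
# ---------------------------------------------------------------------------


def assign_base_constants(
    network: ReactionNetwork,
    params,
    slow_degrade: Iterable[str] | None = None,
) -> ReactionNetwork:
    """Assign the base rate-constant scheme.

    Degradations carry ``k_uni_default`` (1.0) except for the stable giants
    (and optionally the template), which carry ``k_d``.  The two monomer
    dimerization channels are in ratio ``D`` (corner : edge); every other
    synthesis carries ``k_bi_base``.  Inhibitor reactions keep their own
    constants.
    """
    if params.D <= 0:
        raise NetworkError(f"D must be > 0, got {params.D}")
    if slow_degrade is None:
        slow_degrade = {
            sp.id for sp in network.species if sp.is_target and not sp.is_template
        }
    else:
        slow_degrade = set(slow_degrade)
        unknown = slow_degrade - set(network.species_by_id)
        if unknown:
            raise NetworkError(f"unknown slow-degrade species {sorted(unknown)}")
    thr = network.metadata.get("mixing_threshold", 6)
    tpl_n = next((sp.nuclearity for sp in network.species if sp.is_template), None)

    def amorphous(sp: Species) -> bool:
        # structured species (paths, targets, small oligomers, and the
        # hexamer-multiple chain up to the template) are not amorphous
        if sp.lineage != GENERIC or sp.is_target or sp.nuclearity <= thr:
            return False
        if tpl_n is not None and sp.nuclearity % 6 == 0 and sp.nuclearity <= tpl_n:
            return False
        return True

    out = []
    for rx in network.reactions:
        if rx.plain_rate:
            out.append(rx)
            continue
        if rx.kind == "degradation":
            sp = network.species_by_id[rx.reactants[0]]
            if rx.reactants[0] in slow_degrade:
                k = params.k_d
            elif amorphous(sp):
                # an amorphous n-mer has ~n/2 ways to shed a fragment; the
                # coarse accretion ladder lumps them into one channel with a
                # size-proportional constant
                k = params.k_uni_default * sp.nuclearity / 2.0
            else:
                k = params.k_uni_default
        elif set(rx.reactants) == {"Mo1"}:
            # the corner channel carries the D dependence; the reduced
            # (edge) channel sets the reference scale, so the constants are
            # in ratio D (corner : edge)
            k = params.k_bi_base * (params.D if rx.products[0] == "Mo2c" else 1.0)
        else:
            k = params.k_bi_base
        out.append(replace(rx, base_k=k))
    meta = dict(network.metadata)
    meta["rate_scheme"] = {
        "D": params.D,
        "k_bi_base": params.k_bi_base,
        "k_uni_default": params.k_uni_default,
        "k_d": params.k_d,
        "slow_degrade": sorted(slow_degrade),
    }
    return ReactionNetwork(network.species, out, network.max_nuclearity, meta)


@dataclass(frozen=True)
class TemplateRule:
    """Marks syntheses accelerated by a template species.

    A synthesis matches when its product satisfies any provided selector
    (explicit ids, a lineage, or a nuclearity).
    """

    template: str
    product_ids: frozenset[str] | None = None
    product_lineage: str | None = None
    product_nuclearity: int | None = None

    def matches(self, product: Species) -> bool:
        if self.product_ids is not None and product.id in self.product_ids:
            return True
        if self.product_lineage is not None and product.lineage == self.product_lineage:
            return True
        if (
            self.product_nuclearity is not None
            and product.nuclearity == self.product_nuclearity
        ):
            return True
        return False


def default_template_rules(network: ReactionNetwork) -> list[TemplateRule]:
    """The shipped templating scheme.

    {Mo36} accelerates (i) the wheel path it templates and (ii) its own
    oxidized assembly route — the condensation of small fragments into
    {Mo6} and the hexamer chain up to {Mo36} itself.  Rule (ii) is the
    embedded autocatalytic loop: one completed template coordinates the
    fragments of the next copy by molecular recognition, which is what
    makes {Mo36} a self-replicator.
    """
    tpl = next((sp for sp in network.species if sp.is_template), None)
    if tpl is None:
        return []
    route = {"Mo4"} | {
        f"Mo{n}" for n in range(6, tpl.nuclearity + 1, 6)
    }
    route &= set(network.species_by_id)
    return [
        TemplateRule(tpl.id, product_lineage=CORNER),
        TemplateRule(tpl.id, product_ids=frozenset(route)),
    ]


def annotate_templates(
    network: ReactionNetwork,
    rules: Sequence[TemplateRule] | None = None,
) -> ReactionNetwork:
    """Attach template annotations; ``rules=[]`` is the ablation config."""
    if rules is None:
        rules = default_template_rules(network)
    index = network.species_by_id
    for rule in rules:
        if rule.template not in index:
            raise NetworkError(f"unknown template species {rule.template!r}")
        for sid in rule.product_ids or ():
            if sid not in index:
                raise NetworkError(f"unknown product species {sid!r} in rule")
    out = []
    for rx in network.reactions:
        tid = None
        if rx.kind == "synthesis" and not rx.plain_rate:
            prod = index[rx.products[0]]
            for rule in rules:
                if rule.matches(prod):
                    tid = rule.template
                    break
        out.append(replace(rx, template_id=tid))
    meta = dict(network.metadata)
    meta["template_rules"] = [vars(r) | {"product_ids": sorted(r.product_ids or [])} for r in rules]
    return ReactionNetwork(network.species, out, network.max_nuclearity, meta)


def extend_with_inhibitor(
    network: ReactionNetwork,
    binding_k: float,
    release_k: float,
    bound_targets: Sequence[str] = ("Mo6", "Mo36"),
) -> ReactionNetwork:
    """Add a non-cluster inhibitor I with reversible unproductive binding.

    Models carboxylic-acid inhibitors that hydrogen-bond to members of the
    autocatalytic set: ``I + X <-> I.X`` with the given constants, the
    complex I.X taking part in no other reaction.  The inhibitor carries no
    Mo (nuclearity 0), so Mo-mass conservation is untouched.
    """
    if binding_k < 0 or release_k < 0:
        raise NetworkError("inhibitor constants must be >= 0")
    index = network.species_by_id
    missing = [t for t in bound_targets if t not in index]
    if missing:
        raise NetworkError(f"unknown bound_targets {missing}")
    species = list(network.species)
    species.append(Species("I", 0, GENERIC, free_sites=1, mass=1.0))
    reactions = list(network.reactions)
    for t in bound_targets:
        cpx = f"I.{t}"
        species.append(
            Species(cpx, index[t].nuclearity, GENERIC, free_sites=1, inert=True)
        )
        reactions.append(
            Reaction("synthesis", ("I", t), (cpx,), base_k=binding_k, plain_rate=True)
        )
        reactions.append(
            Reaction("degradation", (cpx,), ("I", t), base_k=release_k, plain_rate=True)
        )
    meta = dict(network.metadata)
    meta["inhibitor"] = {
        "binding_k": binding_k,
        "release_k": release_k,
        "bound_targets": list(bound_targets),
    }
    return ReactionNetwork(species, reactions, network.max_nuclearity, meta)


def default_network(
    params,
    max_nuclearity: int = 154,
    targets: Sequence[int] = DEFAULT_TARGETS,
    mixing_threshold: int = 6,
    growth_mode: str = "auto",
    template_rules: Sequence[TemplateRule] | None = None,
    slow_degrade: Iterable[str] | None = None,
) -> ReactionNetwork:
    """Enumerate, rate-assign and template-annotate the standard model."""
    species = enumerate_species(max_nuclearity, targets, mixing_threshold)
    net = enumerate_reactions(species, max_nuclearity, growth_mode, mixing_threshold)
    net = annotate_templates(net, template_rules)
    return assign_base_constants(net, params, slow_degrade)
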