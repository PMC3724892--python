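"""Flavonoid pathway topology: species, enzyme-labeled reactions, validation.

The default network covers the branch of flavonoid biosynthesis downstream of
flavanone 3-hydroxylase (F3H): dihydroflavonols (DHK, DHQ, DHM) are hydroxylated
by F3'H and F3'5'H, converted to flavonol aglycones (KMP, QUE, MYR) by FLS, or
channeled toward anthocyanins via DFR and ANS (DHM -> LCD -> DPH); a
glycosyltransferase (GT) produces the four accumulating end products
(KMPg, QUEg, MYRg, ANT), each of which additionally carries a first-order
reduction (degradation/export) reaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from .errors import TopologyError

INTERMEDIATE = "intermediate"
END_PRODUCT = "end_product"

INFLUX = "influx"
CONVERSION = "conversion"
REDUCTION = "reduction"


@dataclass(frozen=True)
class Species:
    """A modeled metabolite pool."""

    id: str
    role: str  # "intermediate" or "end_product"
    display_name: str = ""

    def __post_init__(self):
        if self.role not in (INTERMEDIATE, END_PRODUCT):
            raise TopologyError(f"species {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """A single network edge.

    kind "influx" has no source (upstream flavanone pool lumped into the rate
    constant); "reduction" has no target and no enzyme; "conversion" has both a
    source and a target and is facilitated by an enzyme.
    """

    id: str
    kind: str
    source: str | None = None
    target: str | None = None
    enzyme: str | None = None

    def __post_init__(self):
        if self.kind == INFLUX:
            ok = self.source is None and self.target is not None
        elif self.kind == CONVERSION:
            ok = (
                self.source is not None
                and self.target is not None
                and self.enzyme is not None
            )
        elif self.kind == REDUCTION:
            ok = (
                self.source is not None
                and self.target is None
                and self.enzyme is None
            )
        else:
            raise TopologyError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if not ok:
            raise TopologyError(
                f"reaction {self.id!r}: fields inconsistent with kind {self.kind!r}"
            )


@dataclass(frozen=True)
class PathwayTopology:
    """Validated reaction network."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    enzymes: tuple[str, ...]

    def __post_init__(self):
        _validate(self)

    # -- convenience accessors -------------------------------------------------

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def end_products(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species if s.role == END_PRODUCT)

    @property
    def intermediates(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species if s.role == INTERMEDIATE)

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise TopologyError(f"unknown species {species_id!r}") from None

    def reactions_of_kind(self, kind: str) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.kind == kind)

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise TopologyError(f"unknown reaction {reaction_id!r}")

    @property
    def reduction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions if r.kind == REDUCTION)

    @property
    def non_reduction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions if r.kind != REDUCTION)

    def to_descriptor(self) -> dict:
        """Plain-dict descriptor (YAML/JSON serializable) round-tripping the network."""
        return {
            "species": [
                {"id": s.id, "role": s.role, "display_name": s.display_name}
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "kind": r.kind,
                    **({"source": r.source} if r.source else {}),
                    **({"target": r.target} if r.target else {}),
                    **({"enzyme": r.enzyme} if r.enzyme else {}),
                }
                for r in self.reactions
            ],
            "enzymes": list(self.enzymes),
        }


def _validate(topo: PathwayTopology) -> None:
    ids = [s.id for s in topo.species]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise TopologyError(f"duplicate species id(s): {dup}")
    rids = [r.id for r in topo.reactions]
    if len(set(rids)) != len(rids):
        dup = sorted({i for i in rids if rids.count(i) > 1})
        raise TopologyError(f"duplicate reaction id(s): {dup}")
    triples = [(r.source, r.target, r.enzyme) for r in topo.reactions]
    if len(set(triples)) != len(triples):
        dup = sorted(
            {str(t) for t in triples if triples.count(t) > 1}
        )
        raise TopologyError(f"duplicate (source, target, enzyme) edge(s): {dup}")

    known = set(ids)
    for r in topo.reactions:
        for endpoint in (r.source, r.target):
            if endpoint is not None and endpoint not in known:
                raise TopologyError(
                    f"reaction {r.id!r} references unknown species {endpoint!r}"
                )
        if r.enzyme is not None and r.enzyme not in topo.enzymes:
            raise TopologyError(
                f"reaction {r.id!r} references unknown enzyme {r.enzyme!r}"
            )

    # acyclicity of the conversion subgraph
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    for r in topo.reactions:
        if r.kind == CONVERSION:
            g.add_edge(r.source, r.target)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise TopologyError(f"conversion edges contain a cycle: {cycle}")

    # every intermediate on a directed path influx -> ... -> some end product
    influx_targets = {r.target for r in topo.reactions if r.kind == INFLUX}
    if not influx_targets:
        raise TopologyError("topology has no influx reaction")
    reachable: set[str] = set()
    for t in influx_targets:
        reachable |= {t} | nx.descendants(g, t)
    ends = set(s.id for s in topo.species if s.role == END_PRODUCT)
    reaches_end = set(ends)
    for e in ends:
        reaches_end |= nx.ancestors(g, e)
    for s in topo.species:
        if s.role == INTERMEDIATE:
            if s.id not in reachable or s.id not in reaches_end:
                raise TopologyError(
                    f"intermediate {s.id!r} is dangling (not on an influx->end-product path)"
                )

    # exactly the end products carry reductions
    reduced = {r.source for r in topo.reactions if r.kind == REDUCTION}
    if reduced != ends:
        raise TopologyError(
            f"reduction reactions must act on exactly the end products; "
            f"got reductions on {sorted(reduced)}, end products {sorted(ends)}"
        )


# -- default network ----------------------------------------------------------

_DEFAULT_SPECIES = [
    ("DHK", INTERMEDIATE, "dihydrokaempferol"),
    ("DHQ", INTERMEDIATE, "dihydroquercetin"),
    ("DHM", INTERMEDIATE, "dihydromyricetin"),
    ("KMP", INTERMEDIATE, "kaempferol aglycone"),
    ("QUE", INTERMEDIATE, "quercetin aglycone"),
    ("MYR", INTERMEDIATE, "myricetin aglycone"),
    ("LCD", INTERMEDIATE, "leucodelphinidin"),
    ("DPH", INTERMEDIATE, "delphinidin aglycone"),
    ("KMPg", END_PRODUCT, "kaempferol glycosides"),
    ("QUEg", END_PRODUCT, "quercetin glycosides"),
    ("MYRg", END_PRODUCT, "myricetin glycosides"),
    ("ANT", END_PRODUCT, "anthocyanins (delphinidin derivatives)"),
]

_DEFAULT_ENZYMES = ("F3H", "F3'H", "F3'5'H", "FLS", "DFR", "ANS", "GT")

# (kind, source, target, enzyme); ids derived below
_DEFAULT_EDGES = [
    (INFLUX, None, "DHK", "F3H"),
    (CONVERSION, "DHK", "DHQ", "F3'H"),
    (CONVERSION, "KMP", "QUE", "F3'H"),
    (CONVERSION, "DHK", "DHQ", "F3'5'H"),
    (CONVERSION, "DHK", "DHM", "F3'5'H"),
    (CONVERSION, "DHQ", "DHM", "F3'5'H"),
    (CONVERSION, "KMP", "QUE", "F3'5'H"),
    (CONVERSION, "KMP", "MYR", "F3'5'H"),
    (CONVERSION, "QUE", "MYR", "F3'5'H"),
    (CONVERSION, "DHK", "KMP", "FLS"),
    (CONVERSION, "DHQ", "QUE", "FLS"),
    (CONVERSION, "DHM", "MYR", "FLS"),
    (CONVERSION, "DHM", "LCD", "DFR"),
    (CONVERSION, "LCD", "DPH", "ANS"),
    (CONVERSION, "KMP", "KMPg", "GT"),
    (CONVERSION, "QUE", "QUEg", "GT"),
    (CONVERSION, "MYR", "MYRg", "GT"),
    (CONVERSION, "DPH", "ANT", "GT"),
    (REDUCTION, "KMPg", None, None),
    (REDUCTION, "QUEg", None, None),
    (REDUCTION, "MYRg", None, None),
    (REDUCTION, "ANT", None, None),
]


def reaction_id(kind: str, source: str | None, target: str | None, enzyme: str | None) -> str:
    """Canonical reaction id: ``ENZ:SRC->TGT`` for enzymatic edges, ``red:SRC`` for reductions."""
    if kind == REDUCTION:
        return f"red:{source}"
    return f"{enzyme}:{source or ''}->{target}"


def build_default_topology(config: dict | str | Path | None = None) -> PathwayTopology:
    """Build the default 12-species, 22-reaction network, or one from a descriptor.

    ``config`` may be a descriptor dict or a path to a YAML/JSON descriptor file
    (see :func:`load_topology`); with no argument the built-in default is returned.
    """
    if config is not None:
        return load_topology(config)
    species = tuple(Species(i, role, name) for i, role, name in _DEFAULT_SPECIES)
    reactions = tuple(
        Reaction(reaction_id(kind, s, t, e), kind, s, t, e)
        for kind, s, t, e in _DEFAULT_EDGES
    )
    return PathwayTopology(species=species, reactions=reactions, enzymes=_DEFAULT_ENZYMES)


def load_topology(config: dict | str | Path) -> PathwayTopology:
    """Build a validated :class:`PathwayTopology` from a descriptor dict or file."""
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith(".json"):
            config = json.loads(text)
        else:
            config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise TopologyError("topology descriptor must be a mapping")
    try:
        species = tuple(
            Species(d["id"], d["role"], d.get("display_name", ""))
            for d in config["species"]
        )
        reactions = tuple(
            Reaction(
                d.get("id")
                or reaction_id(
                    d["kind"], d.get("source"), d.get("target"), d.get("enzyme")
                ),
                d["kind"],
                d.get("source"),
                d.get("target"),
                d.get("enzyme"),
            )
            for d in config["reactions"]
        )
        enzymes = tuple(config["enzymes"])
    except KeyError as e:
        raise TopologyError(f"topology descriptor missing key {e}") from None
    return PathwayTopology(species=species, reactions=reactions, enzymes=enzymes)


def default_topology_path() -> Path:
    """Path to the shipped YAML descriptor reproducing the default network."""
    return Path(__file__).parent / "data" / "default_topology.yaml"
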