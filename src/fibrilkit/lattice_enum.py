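"""Enumeration of polyQ amyloid-core unit-cell architectures.

The minimal repeating unit of the antiparallel polyQ core is a 2x2x2 cell of
eight glutamines: two residues along the strand axis x (the odd/even
side-chain alternation), two strands along the fibril axis z (the antiparallel
repeat) and two β-sheets along the stacking axis y.  The cell contains four
Gln-Gln pairs, indexed by (x, y); each pair adopts one of eight hydrogen-bond
classes describing the (χ1, χ3) orientations that allow a continuous
side-chain amide ladder along z.

A class is coded by three binary attributes:

* ``well_a`` / ``well_b`` — the χ1 orientation of the residue in strand z=0
  and z=1 of the pair, written in the laboratory frame as the equivalent χ1
  rotamer well (``p`` ≈ +62°, ``m`` ≈ −65°) of a +x-running strand.  The
  intrinsic well of a residue on a −x-running strand is the opposite tag.
* ``direction`` — the donor→acceptor direction of the amide ladder along the
  fibril axis (``u`` = +z, ``d`` = −z).

With four pairs and eight classes the raw space holds 8^4 = 4096 candidate
architectures.  Lattice symmetry (declared as a group of slot permutations
with induced class relabelings) reduces these to unique orbit representatives,
and the ssNMR strand-uniformity filter — every strand is built from a single
conformer type — reduces the catalog to the experimentally feasible set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = [
    "HBondClass",
    "UnitCellCandidate",
    "GroupElement",
    "SymmetryGroup",
    "default_alphabet",
    "default_group",
    "load_alphabet",
    "load_group",
    "enumerate_raw_candidates",
    "canonicalize",
    "unique_candidates",
    "apply_strand_uniformity_filter",
    "export_catalog",
    "read_catalog",
]

#: slot order used for encoding and lexicographic tie-breaking: x fastest, then y
PAIR_SLOTS = ((0, 0), (1, 0), (0, 1), (1, 1))
_SLOT_INDEX = {s: i for i, s in enumerate(PAIR_SLOTS)}

#: nominal χ1 well centres (degrees) for the p/m rotamer basins
WELL_CENTERS = {"p": 62.0, "m": -65.0}


class ConfigurationError(ValueError):
    """Raised for invalid alphabets, groups or candidate codes."""


@dataclass(frozen=True)
class HBondClass:
    """One of the eight (χ1, χ3) orientation classes of a Gln-Gln pair."""

    label: str
    well_a: str  # lab-frame χ1 orientation tag of the z=0 residue: 'p' or 'm'
    well_b: str  # lab-frame χ1 orientation tag of the z=1 residue
    direction: str  # amide-ladder donor direction along z: 'u' (+z) or 'd' (-z)
    representative_chi1_deg: float = 0.0
    representative_chi3_deg: float = 0.0

    def __post_init__(self):
        if self.well_a not in ("p", "m") or self.well_b not in ("p", "m"):
            raise ConfigurationError(f"invalid well tags in class {self.label!r}")
        if self.direction not in ("u", "d"):
            raise ConfigurationError(f"invalid direction in class {self.label!r}")


@dataclass(frozen=True)
class UnitCellCandidate:
    """A full assignment of H-bond classes to the four pairs of the cell."""

    pair_assignment: tuple  # class labels in PAIR_SLOTS order
    strand_conformers: dict | None = None  # {(z, y): 'a'|'b'} on filter survivors
    canonical_id: str | None = None

    def __post_init__(self):
        if len(self.pair_assignment) != 4:
            raise ConfigurationError("a candidate carries exactly 4 pair assignments")

    @property
    def encoding(self) -> str:
        return "|".join(self.pair_assignment)

    def pair_class(self, x: int, y: int) -> str:
        return self.pair_assignment[_SLOT_INDEX[(x, y)]]


@dataclass(frozen=True)
class GroupElement:
    """A symmetry operation: pair-slot permutation plus induced class action.

    ``pair_perm[i]`` is the source slot whose class lands in slot ``i``.
    The class action is the composition of three optional involutions:
    swapping the two within-pair wells (z-reversal), flipping both orientation
    tags p↔m (strand-direction reversal in the lab frame) and flipping the
    ladder direction u↔d (z-axis reversal).
    """

    name: str
    pair_perm: tuple
    swap_pair: bool = False
    flip_orientation: bool = False
    flip_direction: bool = False

    def __post_init__(self):
        if sorted(self.pair_perm) != [0, 1, 2, 3]:
            raise ConfigurationError(
                f"group element {self.name!r} is not a bijection on pair slots")

    def act_label(self, cls: HBondClass) -> tuple:
        wa, wb, d = cls.well_a, cls.well_b, cls.direction
        if self.swap_pair:
            wa, wb = wb, wa
        if self.flip_orientation:
            wa = "m" if wa == "p" else "p"
            wb = "m" if wb == "p" else "p"
        if self.flip_direction:
            d = "d" if d == "u" else "u"
        return wa, wb, d

    def compose(self, other: "GroupElement") -> "GroupElement":
        """Element acting as self∘other (apply ``other`` first)."""
        perm = tuple(other.pair_perm[self.pair_perm[i]] for i in range(4))
        return GroupElement(
            name=f"{self.name}*{other.name}",
            pair_perm=perm,
            swap_pair=self.swap_pair ^ other.swap_pair,
            flip_orientation=self.flip_orientation ^ other.flip_orientation,
            flip_direction=self.flip_direction ^ other.flip_direction,
        )

    def key(self):
        return (self.pair_perm, self.swap_pair, self.flip_orientation,
                self.flip_direction)


class SymmetryGroup:
    """Finite group generated by the declared elements, closed at load."""

    def __init__(self, generators, max_order: int = 512):
        identity = GroupElement("e", (0, 1, 2, 3))
        elements = {identity.key(): identity}
        frontier = list(generators)
        while frontier:
            new = []
            for g in frontier:
                if g.key() not in elements:
                    elements[g.key()] = g
            for g in frontier:
                for h in elements.values():
                    for prod in (g.compose(h), h.compose(g)):
                        if prod.key() not in elements and all(
                                prod.key() != n.key() for n in new):
                            new.append(prod)
            frontier = new
            if len(elements) + len(new) > max_order:
                raise ConfigurationError("symmetry group closure exceeds max order")
        self.generators = list(generators)
        self.elements = list(elements.values())
        self._verify_closure()

    def _verify_closure(self):
        keys = {g.key() for g in self.elements}
        for g, h in itertools.product(self.elements, repeat=2):
            if g.compose(h).key() not in keys:
                raise ConfigurationError("group closure verification failed")

    def __len__(self):
        return len(self.elements)

    def apply(self, element: GroupElement, candidate: UnitCellCandidate,
              alphabet) -> UnitCellCandidate:
        by_label = {c.label: c for c in alphabet}
        by_code = {(c.well_a, c.well_b, c.direction): c.label for c in alphabet}
        labels = []
        for i in range(4):
            src = candidate.pair_assignment[element.pair_perm[i]]
            try:
                cls = by_label[src]
            except KeyError:
                raise ConfigurationError(f"candidate uses unknown class {src!r}")
            labels.append(by_code[element.act_label(cls)])
        return UnitCellCandidate(pair_assignment=tuple(labels))

    def orbit(self, candidate: UnitCellCandidate, alphabet):
        return [self.apply(g, candidate, alphabet) for g in self.elements]


def default_alphabet():
    """The eight-class alphabet of side-chain H-bond pair orientations."""
    classes = []
    for wa in ("p", "m"):
        for wb in ("p", "m"):
            for d in ("u", "d"):
                chi3 = 45.0 if d == "u" else -135.0
                classes.append(HBondClass(
                    label=f"{wa}{wb}{d}",
                    well_a=wa, well_b=wb, direction=d,
                    representative_chi1_deg=WELL_CENTERS[wa],
                    representative_chi3_deg=chi3,
                ))
    return classes


def default_group() -> SymmetryGroup:
    """Lattice symmetry of the antiparallel cross-β cell.

    Generators: translation by one sheet along y; translation by one strand
    along z re-expressed in the cell frame (pair swap + orientation flip,
    because the shifted strand runs the other way along x); the 2-fold
    rotation about the fibril axis z; and the 2-fold rotation about the
    strand axis x.  Their compositions include the remaining in-plane 2-fold
    about y and the screw translation along x; the closed group has order 16.
    """
    perm = _perm_from_map
    return SymmetryGroup([
        GroupElement("translate_y", perm(lambda x, y: (x, 1 - y))),
        GroupElement("translate_z", perm(lambda x, y: (1 - x, 1 - y)),
                     swap_pair=True, flip_orientation=True),
        GroupElement("rotate2_z", perm(lambda x, y: (1 - x, 1 - y)),
                     flip_orientation=True),
        GroupElement("rotate2_x", perm(lambda x, y: (x, 1 - y)),
                     swap_pair=True, flip_direction=True),
    ])


def _perm_from_map(f):
    # pair_perm[i] = index of the slot whose class moves into slot i
    return tuple(_SLOT_INDEX[f(*slot)] for slot in PAIR_SLOTS)


def load_alphabet(path) -> list:
    """Read a class alphabet from a YAML config file."""
    data = yaml.safe_load(Path(path).read_text())
    entries = data["alphabet"] if isinstance(data, dict) else data
    if not entries:
        raise ConfigurationError("empty alphabet configuration")
    return [HBondClass(**e) for e in entries]


def load_group(path) -> SymmetryGroup:
    """Read symmetry-group generators from a YAML config file."""
    data = yaml.safe_load(Path(path).read_text())
    gens = []
    for e in data["generators"]:
        perm_map = e["pair_perm"]  # e.g. {"00": "10", ...}, target<-source
        perm = tuple(
            _SLOT_INDEX[tuple(int(c) for c in perm_map[f"{x}{y}"])]
            for (x, y) in PAIR_SLOTS
        )
        gens.append(GroupElement(
            name=e.get("name", "g"),
            pair_perm=perm,
            swap_pair=bool(e.get("swap_pair", False)),
            flip_orientation=bool(e.get("flip_orientation", False)),
            flip_direction=bool(e.get("flip_direction", False)),
        ))
    return SymmetryGroup(gens)


def enumerate_raw_candidates(alphabet) -> list:
    """All |alphabet|^4 assignments, lexicographic in alphabet order."""
    if not alphabet:
        raise ConfigurationError("alphabet must be non-empty")
    labels = [c.label for c in alphabet]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate class labels in alphabet")
    return [UnitCellCandidate(pair_assignment=combo)
            for combo in itertools.product(labels, repeat=4)]


def canonicalize(candidate: UnitCellCandidate, group: SymmetryGroup,
                 alphabet) -> str:
    """Canonical id: the lexicographically minimal encoding over the orbit."""
    order = {c.label: i for i, c in enumerate(alphabet)}
    best = None
    for image in group.orbit(candidate, alphabet):
        key = tuple(order[l] for l in image.pair_assignment)
        if best is None or key < best[0]:
            best = (key, image.encoding)
    return best[1]


def unique_candidates(candidates, group: SymmetryGroup, alphabet) -> list:
    """One representative per orbit, in lexicographic catalog order.

    The representative is the orbit's canonical form itself, so the returned
    candidates satisfy ``encoding == canonical_id``.
    """
    seen = {}
    for cand in candidates:
        cid = canonicalize(cand, group, alphabet)
        if cid not in seen:
            seen[cid] = UnitCellCandidate(
                pair_assignment=tuple(cid.split("|")), canonical_id=cid)
    order = {c.label: i for i, c in enumerate(alphabet)}
    return sorted(seen.values(),
                  key=lambda c: tuple(order[l] for l in c.pair_assignment))


def _strand_conformers(candidate: UnitCellCandidate, alphabet) -> dict:
    """Conformer tag per strand (z, y); 'a' = pt20-type (p well), 'b' = mt-30.

    The z=1 strand runs along −x, so its intrinsic χ1 well is the flip of the
    lab-frame orientation tag stored in the class.
    """
    by_label = {c.label: c for c in alphabet}
    tags = {}
    for y in (0, 1):
        cls = by_label[candidate.pair_class(0, y)]
        tags[(0, y)] = "a" if cls.well_a == "p" else "b"
        tags[(1, y)] = "a" if cls.well_b == "m" else "b"
    return tags


def apply_strand_uniformity_filter(candidates, alphabet) -> list:
    """Keep candidates whose strands are conformer-uniform along x.

    ssNMR chemical shifts show that consecutive residues of one strand share a
    single backbone/side-chain conformation, so the two pair classes of a
    sheet must agree in both well tags (only the ladder direction may differ
    between the odd and even columns).  Survivors receive their derived
    strand-conformer map; the operation is idempotent.
    """
    by_label = {c.label: c for c in alphabet}
    out = []
    for cand in candidates:
        try:
            pairs = {(x, y): by_label[cand.pair_class(x, y)]
                     for x in (0, 1) for y in (0, 1)}
        except KeyError as exc:
            raise ConfigurationError(
                f"candidate {cand.encoding} uses undefined pair class {exc}")
        uniform = all(
            pairs[(0, y)].well_a == pairs[(1, y)].well_a
            and pairs[(0, y)].well_b == pairs[(1, y)].well_b
            for y in (0, 1)
        )
        if uniform:
            out.append(replace(cand, strand_conformers=_strand_conformers(cand, alphabet)))
    return out


CATALOG_VERSION = "fibrilkit-catalog v1"
_PAIR_COLS = [f"pair_xy{x}{y}" for (x, y) in PAIR_SLOTS]
_STRAND_COLS = [f"strand_z{z}y{y}" for y in (0, 1) for z in (0, 1)]


def export_catalog(candidates, path) -> None:
    """Write a versioned tab-delimited catalog; round-trips losslessly."""
    path = Path(path)
    lines = [f"# {CATALOG_VERSION}",
             "\t".join(["canonical_id"] + _PAIR_COLS + _STRAND_COLS)]
    for cand in candidates:
        row = [cand.canonical_id or cand.encoding]
        row += list(cand.pair_assignment)
        sc = cand.strand_conformers or {}
        row += [sc.get((z, y), "-") for y in (0, 1) for z in (0, 1)]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_catalog(path) -> list:
    """Read a catalog written by :func:`export_catalog`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ConfigurationError("missing catalog version header")
    header = lines[1].split("\t")
    expected = ["canonical_id"] + _PAIR_COLS + _STRAND_COLS
    if header != expected:
        raise ConfigurationError("unexpected catalog columns")
    out = []
    for line in lines[2:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        strand_cells = cells[5:9]
        conformers = None
        if all(c in ("a", "b") for c in strand_cells):
            conformers = {(z, y): strand_cells[2 * y + z]
                          for y in (0, 1) for z in (0, 1)}
        out.append(UnitCellCandidate(
            pair_assignment=tuple(cells[1:5]),
            strand_conformers=conformers,
            canonical_id=cells[0],
        ))
    return out
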