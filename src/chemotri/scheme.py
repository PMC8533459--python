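"""Combinatorial rule model of orcinol depside and depsidone assembly.

Each aromatic ring of an orcinol depside derives from one polyketide chain:
an acyl starter of 2, 4, 6 or 8 carbons (acetyl-CoA or a FAS-delivered
acyl-ACP) extended by three — sometimes four — malonyl-CoA units, then
cyclised.  After cyclisation the ring side chain has

    side_chain_carbons = starter_carbons + 2 * (malonyl_extensions - 3) - 1

carbons (always odd: 1, 3, 5 or 7), and a fourth malonyl extension leaves a
ß-keto group on the side chain (the carbonyl oxygen of the starter).  The
PKS esterifies the A-ring carboxyl with the B-ring 4'-OH and releases the
depside; a dedicated CytP450 may then oxidatively couple the A-ring C2-OH to
the B-ring 5' carbon, the extra ether bond that turns the depside into the
depsidone.  Olivetoric acid (C7/C5 side chains, ß-keto on A) and its
depsidone physodic acid are the worked example; lecanoric acid is the
all-acetyl (C1/C1) case.

The model is structural only: no stereochemistry, masses or kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import ChemotriError

__all__ = [
    "RingSpec", "CompoundSpec", "build_ring", "assemble_depside",
    "depsidonize", "starter_source",
]

ALLOWED_STARTERS = (2, 4, 6, 8)
ALLOWED_EXTENSIONS = (3, 4)


@dataclass(frozen=True)
class RingSpec:
    """One orcinol ring: starter length, extension count, derived side chain."""

    starter_carbons: int
    malonyl_extensions: int

    def __post_init__(self) -> None:
        if self.starter_carbons not in ALLOWED_STARTERS:
            raise ChemotriError(
                f"starter must be one of {ALLOWED_STARTERS} carbons")
        if self.malonyl_extensions not in ALLOWED_EXTENSIONS:
            raise ChemotriError(
                f"malonyl extensions must be in {ALLOWED_EXTENSIONS}")

    @property
    def side_chain_carbons(self) -> int:
        return self.starter_carbons + 2 * (self.malonyl_extensions - 3) - 1

    @property
    def beta_keto(self) -> bool:
        return self.malonyl_extensions == 4

    def as_dict(self) -> dict:
        return {"starter_carbons": self.starter_carbons,
                "malonyl_extensions": self.malonyl_extensions,
                "side_chain_carbons": self.side_chain_carbons,
                "beta_keto": self.beta_keto}


@dataclass(frozen=True)
class CompoundSpec:
    """A depside or depsidone: two rings, the ester bond, optional ether."""

    ring_a: RingSpec
    ring_b: RingSpec
    ether_bond: bool = False
    #: fixed ester linkage: A-ring carboxyl to B-ring 4'-OH
    ester_bond: str = "A-carboxyl->B-4'-OH"

    @property
    def compound_class(self) -> str:
        return "depsidone" if self.ether_bond else "depside"

    def as_dict(self) -> dict:
        return {"ring_a": self.ring_a.as_dict(),
                "ring_b": self.ring_b.as_dict(),
                "ester_bond": self.ester_bond,
                "ether_bond": self.ether_bond,
                "class": self.compound_class}


def build_ring(starter_carbons: int, malonyl_extensions: int) -> RingSpec:
    """Build one orcinol ring spec from starter length and extension count."""
    return RingSpec(starter_carbons=starter_carbons,
                    malonyl_extensions=malonyl_extensions)


def assemble_depside(ring_a: RingSpec, ring_b: RingSpec) -> CompoundSpec:
    """Esterify two rings (A carboxyl to B 4'-OH) and release the depside."""
    return CompoundSpec(ring_a=ring_a, ring_b=ring_b, ether_bond=False)


def depsidonize(compound: CompoundSpec) -> CompoundSpec:
    """Add the CytP450-made ether bond (A C2-OH to B 5'-C): depsidone.

    Ring specs are preserved exactly; only the bond set changes.  Raises if
    the input is already a depsidone.
    """
    if compound.ether_bond:
        raise ChemotriError("compound is already a depsidone")
    return replace(compound, ether_bond=True)


def starter_source(compound: CompoundSpec,
                   fas_available: bool) -> dict[str, str]:
    """Which machinery supplies each ring's starter in a given host.

    Acetyl (C2) starters are the PKS default and always reachable; longer
    acyl starters are delivered by a dedicated metabolite FAS directly
    ACP-to-ACP, never taken up as free acyl-CoAs — so without such a FAS
    (e.g. in a yeast host) rings with C4/C6/C8 starters are unreachable and
    the PKS falls back to making the all-acetyl product.
    """
    out = {}
    for name, ring in (("ring_a", compound.ring_a),
                       ("ring_b", compound.ring_b)):
        if ring.starter_carbons == 2:
            out[name] = "acetyl-CoA-default"
        elif fas_available:
            out[name] = "FAS-delivered"
        else:
            out[name] = "unreachable-in-host"
    return out
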