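"""Built-in example networks.

Two archetypal "chemical oscillators" — the Brusselator (open, autocatalytic)
and a closed trimolecular cyclic-competition system — plus two linear test
networks.  Rate constants are package defaults chosen to place each fixture
in its oscillatory regime; they are plain config values and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import ReactionNetwork, load_network

__all__ = ["fixture", "Fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class Fixture:
    name: str
    network: ReactionNetwork
    init: tuple
    notes: str


def _brusselator(c1=1.0, c2=3.0, c3=1.0, c4=1.0, omega=10.0) -> ReactionNetwork:
    # 2X+Y -> 3X (rate c1/omega^2), X -> Y (c2), 0 -> X (c3*omega), X -> 0 (c4)
    return load_network({
        "species": ["X", "Y"],
        "omega": omega,
        "reactions": [
            {"reactants": {"X": 2, "Y": 1}, "products": {"X": 3},
             "rate": c1, "omega_exponent": -2},
            {"reactants": {"X": 1}, "products": {"Y": 1}, "rate": c2},
            {"reactants": {}, "products": {"X": 1}, "rate": c3,
             "omega_exponent": 1},
            {"reactants": {"X": 1}, "products": {}, "rate": c4},
        ],
    })


def _trimolecular(alpha=1.0, beta=1.0, gamma=1.0) -> ReactionNetwork:
    # A+B -> 2A, B+C -> 2B, C+A -> 2C: cyclic competition, conserves A+B+C
    return load_network({
        "species": ["A", "B", "C"],
        "reactions": [
            {"reactants": {"A": 1, "B": 1}, "products": {"A": 2}, "rate": alpha},
            {"reactants": {"B": 1, "C": 1}, "products": {"B": 2}, "rate": beta},
            {"reactants": {"C": 1, "A": 1}, "products": {"C": 2}, "rate": gamma},
        ],
    })


def _birth_death(birth=1.0, death=1.0, omega=1.0) -> ReactionNetwork:
    return load_network({
        "species": ["A"],
        "omega": omega,
        "reactions": [
            {"reactants": {}, "products": {"A": 1}, "rate": birth,
             "omega_exponent": 1},
            {"reactants": {"A": 1}, "products": {}, "rate": death},
        ],
    })


def _two_state(k_ab=1.0, k_ba=1.0) -> ReactionNetwork:
    # A <-> B, conserves A+B; with total 1 this is the symmetric 2-state chain
    return load_network({
        "species": ["A", "B"],
        "reactions": [
            {"reactants": {"A": 1}, "products": {"B": 1}, "rate": k_ab},
            {"reactants": {"B": 1}, "products": {"A": 1}, "rate": k_ba},
        ],
    })


def fixture(name: str, **params) -> Fixture:
    """Return a named example network with its recommended initial state.

    Names: ``brusselator``, ``trimolecular``, ``birth-death``, ``two-state``.
    Keyword arguments override the default rate constants.
    """
    if name == "brusselator":
        return Fixture(name, _brusselator(**params), (1, 1),
                       "open autocatalytic oscillator; default constants put "
                       "the rate equations past their Hopf point")
    if name == "trimolecular":
        return Fixture(name, _trimolecular(**params), (10, 5, 5),
                       "closed cyclic competition A+B->2A, B+C->2B, C+A->2C; "
                       "total copy number conserved, unit default rates")
    if name == "birth-death":
        return Fixture(name, _birth_death(**params), (0,),
                       "linear birth-death process; moments closed exactly")
    if name == "two-state":
        return Fixture(name, _two_state(**params), (1, 0),
                       "symmetric two-state chain; generator [[-1,1],[1,-1]] "
                       "on total 1")
    raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_NAMES)}")


FIXTURE_NAMES = ("brusselator", "trimolecular", "birth-death", "two-state")
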