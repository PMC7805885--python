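"""Core model definitions: parameters, actions, strategies, and round rules.

The model is a noisy iterated prisoner's dilemma. Each round both players
choose an intended action; with probability ``a`` the realized action is the
opposite of the intended one. After the round, a player whose realized action
was DEFECT may apologize (paying a cost), and the partner may believe the
apology. Conditional strategies (grim trigger and its guilt-prone variant)
carry a within-encounter mode, COOPERATIVE or PUNISHING, that summarizes all
history they condition on; PUNISHING is absorbing.

Strategies
----------
C   unconditional cooperation
D   unconditional defection
GT  grim trigger: cooperate until the partner defects once, then defect forever
GP  guilt-prone grim trigger: grim trigger that apologizes (cost ``c``) after
    its own defections while cooperative, and forgives partners whose
    apologies it believes; guilt-prone apologies are always believed
F   faker: always defect, apologize (cost ``d``) after defecting; a faker's
    apology is believed with probability ``p``
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace


class Action(enum.Enum):
    COOPERATE = "C"
    DEFECT = "D"

    def flipped(self) -> "Action":
        """The erroneous realization of this action."""
        return Action.DEFECT if self is Action.COOPERATE else Action.COOPERATE


class Strategy(str, enum.Enum):
    C = "C"
    D = "D"
    GT = "GT"
    GP = "GP"
    F = "F"

    def __str__(self) -> str:  # plain labels in tables and CLI output
        return self.value


#: Strategies whose intended action depends on the within-encounter mode.
CONDITIONAL_STRATEGIES = (Strategy.GT, Strategy.GP)

ALL_STRATEGIES = (Strategy.C, Strategy.D, Strategy.GT, Strategy.GP, Strategy.F)


class Mode(enum.Enum):
    COOPERATIVE = "cooperative"
    PUNISHING = "punishing"


class GPApologyPolicy(str, enum.Enum):
    """When the guilt-prone type apologizes.

    ``ALWAYS`` (default): after every realized defection, including intended
    punitive defections — guilt attaches to the act itself. This literal
    reading makes high apology costs genuinely expensive for guilt-prone
    players locked in punishment, which is what caps the benefit of costly
    apology at an interior optimum.
    ``IF_COOPERATIVE``: only for defections committed while in COOPERATIVE
    mode (accidents); punitive defections are intended, not regretted.
    """

    ALWAYS = "always"
    IF_COOPERATIVE = "if_cooperative"


class FakerApologyPolicy(str, enum.Enum):
    """When a faker issues its (costly) apology after defecting.

    ``ALWAYS`` (default): after every realized defection, unconditionally —
    the faker's apology habit is as literal as its defection habit.
    ``IF_PARTNER_COOPERATED``: only when the partner's realized action that
    round was COOPERATE — once a partner has turned punitive there is nobody
    left worth convincing, so the faker stops paying.
    """

    ALWAYS = "always"
    IF_PARTNER_COOPERATED = "if_partner_cooperated"


class ParameterError(ValueError):
    """Raised for parameter values outside the model's admissible ranges."""


@dataclass(frozen=True)
class ModelParams:
    """The five scalar model parameters.

    Parameters
    ----------
    n : float
        Continuation probability: after each round another round is played
        with probability ``n``; expected encounter length is 1/(1-n).
        Must satisfy 0 <= n < 1.
    a : float
        Per-action execution error probability, 0 <= a < 0.5.
    p : float
        Probability a faker's apology is believed ("fakeability"),
        0 < p <= 1. Guilt-prone apologies are always believed.
    c : float
        Apology cost paid by the guilt-prone type, c >= 0.
    d : float
        Apology cost paid by the faker, d >= 0. The model's asymmetric-cost
        regime has d >= c (fakers pay at least as much); d < c triggers a
        warning, not an error.
    """

    n: float = 0.95
    a: float = 0.01
    p: float = 0.95
    c: float = 0.4
    d: float = 0.4
    gp_apology_policy: GPApologyPolicy = GPApologyPolicy.ALWAYS
    faker_apology_policy: FakerApologyPolicy = FakerApologyPolicy.ALWAYS

    def __post_init__(self) -> None:
        if not 0.0 <= self.n < 1.0:
            raise ParameterError(f"continuation probability n must be in [0, 1), got {self.n}")
        if not 0.0 <= self.a < 0.5:
            raise ParameterError(f"error rate a must be in [0, 0.5), got {self.a}")
        if not 0.0 < self.p <= 1.0:
            raise ParameterError(f"fakeability p must be in (0, 1], got {self.p}")
        if self.c < 0.0:
            raise ParameterError(f"apology cost c must be >= 0, got {self.c}")
        if self.d < 0.0:
            raise ParameterError(f"apology cost d must be >= 0, got {self.d}")
        if self.d < self.c:
            warnings.warn(
                f"faker cost d={self.d} < guilt-prone cost c={self.c}; the asymmetric-cost "
                "regime of the model assumes d >= c",
                UserWarning,
                stacklevel=3,
            )

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def apology_cost(self, strategy: Strategy) -> float:
        """Cost the given strategy pays per apology issued (0 for non-apologizers)."""
        if strategy is Strategy.GP:
            return self.c
        if strategy is Strategy.F:
            return self.d
        return 0.0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "a": self.a,
            "p": self.p,
            "c": self.c,
            "d": self.d,
            "gp_apology_policy": self.gp_apology_policy.value,
            "faker_apology_policy": self.faker_apology_policy.value,
        }


# ---------------------------------------------------------------------------
# Stage game
# ---------------------------------------------------------------------------

#: Prisoner's dilemma stage constants, T > R > P > S.
TEMPTATION = 3.0  # defect against a cooperator
REWARD = 2.0      # mutual cooperation
PUNISHMENT = 1.0  # mutual defection
SUCKER = 0.0      # cooperate against a defector


def stage_payoff(own: Action, other: Action) -> float:
    """One-round prisoner's dilemma payoff to the ``own`` player."""
    if own is Action.COOPERATE:
        return REWARD if other is Action.COOPERATE else SUCKER
    return TEMPTATION if other is Action.COOPERATE else PUNISHMENT


# ---------------------------------------------------------------------------
# Round rules
# ---------------------------------------------------------------------------


def intended_action(strategy: Strategy, mode: Mode) -> Action:
    """The action a strategy intends in the given mode (before execution error)."""
    if strategy is Strategy.C:
        return Action.COOPERATE
    if strategy in (Strategy.D, Strategy.F):
        return Action.DEFECT
    # GT and GP: grim-trigger behavior driven by mode
    return Action.COOPERATE if mode is Mode.COOPERATIVE else Action.DEFECT


def realize_action(intended: Action, a: float, draw: float) -> Action:
    """Apply the execution error: the intended action flips when ``draw < a``."""
    if not 0.0 <= a < 0.5:
        raise ParameterError(f"error rate a must be in [0, 0.5), got {a}")
    return intended.flipped() if draw < a else intended


def apology_issued(
    strategy: Strategy,
    mode: Mode,
    own_realized: Action,
    partner_realized: Action,
    gp_policy: GPApologyPolicy = GPApologyPolicy.ALWAYS,
    faker_policy: FakerApologyPolicy = FakerApologyPolicy.ALWAYS,
) -> bool:
    """Whether the player apologizes at the end of the round.

    Both apologizing strategies apologize after their own realized
    defections; by default unconditionally (see the policy enums for the
    restricted variants). C, D and GT never apologize.
    """
    if own_realized is not Action.DEFECT:
        return False
    if strategy is Strategy.GP:
        if gp_policy is GPApologyPolicy.ALWAYS:
            return True
        return mode is Mode.COOPERATIVE
    if strategy is Strategy.F:
        if faker_policy is FakerApologyPolicy.ALWAYS:
            return True
        return partner_realized is Action.COOPERATE
    return False


def apology_believed(apologizer: Strategy, p: float, draw: float) -> bool:
    """Whether an issued apology is believed.

    Guilt acts as its own signal: a guilt-prone apology is always believed.
    A faker's apology is believed with probability ``p`` (``draw < p``).
    """
    if apologizer is Strategy.GP:
        return True
    return draw < p


def update_mode(
    strategy: Strategy,
    mode: Mode,
    partner_realized: Action,
    believed_apology_received: bool,
) -> Mode:
    """End-of-round mode update, effective from the next round.

    PUNISHING is absorbing. GT turns punitive on any partner defection and
    ignores apologies. GP forgives a partner defection accompanied by a
    believed apology; an unapologized-for (or disbelieved) defection triggers
    permanent punishment.
    """
    if strategy not in CONDITIONAL_STRATEGIES:
        return mode
    if mode is Mode.PUNISHING:
        return Mode.PUNISHING
    if partner_realized is Action.DEFECT:
        if strategy is Strategy.GP and believed_apology_received:
            return Mode.COOPERATIVE
        return Mode.PUNISHING
    return Mode.COOPERATIVE


def effective_modes(strategy: Strategy) -> tuple[Mode, ...]:
    """The modes a strategy's behavior can actually depend on."""
    if strategy in CONDITIONAL_STRATEGIES:
        return (Mode.COOPERATIVE, Mode.PUNISHING)
    return (Mode.COOPERATIVE,)
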