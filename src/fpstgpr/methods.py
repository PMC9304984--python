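"""Contraceptive method codes and effectiveness-based prioritization.

Fourteen method types are tracked: ten modern (female and male
sterilisation, IUD, injections, implants, pill, condom, diaphragm,
emergency contraception, other modern) and four traditional (LAM, rhythm,
withdrawal, other traditional). When a woman reports more than one current
method, a single method of choice is assigned by effectiveness priority;
every modern method outranks every traditional one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MODERN_METHODS: tuple[str, ...] = (
    "female_sterilisation",
    "male_sterilisation",
    "iud",
    "injections",
    "implants",
    "pill",
    "condom",
    "diaphragm",
    "emergency_contraception",
    "other_modern",
)

TRADITIONAL_METHODS: tuple[str, ...] = (
    "lam",
    "rhythm",
    "withdrawal",
    "other_traditional",
)

ALL_METHODS: tuple[str, ...] = MODERN_METHODS + TRADITIONAL_METHODS

N_METHODS = len(ALL_METHODS)


@dataclass(frozen=True)
class MethodPriority:
    """Ordered method list, highest priority first, with modern flags.

    The default ordering is the effectiveness prioritization: the ten
    modern methods in their stated order, then the four traditional
    methods in listing order.
    """

    order: tuple[str, ...] = ALL_METHODS
    modern: frozenset[str] = field(default_factory=lambda: frozenset(MODERN_METHODS))

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(ALL_METHODS):
            raise ValueError("priority order must contain each of the 14 method codes exactly once")
        ranks = {m: i for i, m in enumerate(self.order)}
        if max(ranks[m] for m in self.modern) > min(
            ranks[m] for m in self.order if m not in self.modern
        ):
            raise ValueError("every modern method must precede every traditional method")

    def rank(self, code: str) -> int:
        try:
            return self.order.index(code)
        except ValueError:
            raise KeyError(f"unknown method code: {code!r}") from None

    def is_modern(self, code: str) -> bool:
        if code not in ALL_METHODS:
            raise KeyError(f"unknown method code: {code!r}")
        return code in self.modern


DEFAULT_PRIORITY = MethodPriority()


def prioritize_method(methods_reported, priority: MethodPriority = DEFAULT_PRIORITY):
    """Return the single method of choice from a set of reported codes.

    The highest-priority (most effective) reported method wins; an IUD
    user who also reports condoms counts as an IUD user. An empty set
    means the woman is a non-user and ``None`` is returned.

    Raises
    ------
    KeyError
        If any reported code is not one of the 14 known methods.
    """
    methods = set(methods_reported)
    unknown = methods.difference(ALL_METHODS)
    if unknown:
        raise KeyError(f"unknown method code(s): {sorted(unknown)}")
    if not methods:
        return None
    return min(methods, key=priority.rank)
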