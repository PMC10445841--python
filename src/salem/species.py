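"""The twelve parameterised species and their standard abbreviations."""
from __future__ import annotations

import enum


class Species(str, enum.Enum):
    """Species handled by the simulator, keyed by their field abbreviation.

    The abbreviations ("Qu. ro.", "Pi. ab.", ...) are the ones used across
    all shipped parameter files and in scenario configuration files.
    """

    QUERCUS_ROBUR = "Qu. ro."
    QUERCUS_PETRAEA = "Qu. pe."
    QUERCUS_PUBESCENS = "Qu. pu."
    FAGUS_SYLVATICA = "Fa. sy."
    PINUS_PINASTER = "Pi. pi."
    PINUS_SYLVESTRIS = "Pi. sy."
    PINUS_LARICIO = "Pi. la."
    PINUS_NIGRA = "Pi. ni."
    PINUS_HALEPENSIS = "Pi. ha."
    ABIES_ALBA = "Ab. al."
    PICEA_ABIES = "Pi. ab."
    PSEUDOTSUGA_MENZIESII = "Ps. me."

    @classmethod
    def from_code(cls, code: str | Species) -> "Species":
        """Resolve an abbreviation (or an existing member) to a Species.

        Raises a ``ValueError`` naming the offending code for anything that is
        not one of the twelve known abbreviations.
        """
        if isinstance(code, cls):
            return code
        try:
            return cls(code)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown species code {code!r}; valid codes are: {valid}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_SPECIES: tuple[Species, ...] = tuple(Species)
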