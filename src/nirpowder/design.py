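"""Nitrogen-equivalence adulteration design.

Enumerates the full mixture experiment for three protein powders (whey,
beef, pea) adulterated with up to four nitrogen-rich compounds — urea (U),
glycine (G), taurine (T) and melamine (M) — at six melamine-equivalent
dose levels plus an unadulterated control, in triplicate.

The dosing rule is *nitrogen equivalence*: every mixture at a given level
carries the same mass of added (non-protein) nitrogen as pure melamine at
that level's %w/w. Within a mixture the added nitrogen is split equally
among the member adulterants, so low-nitrogen compounds (taurine, glycine)
appear at much higher mass fractions than melamine or urea.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AdulterantSpec",
    "MixtureCombo",
    "SampleRecord",
    "DEFAULT_ADULTERANTS",
    "PROTEINS",
    "CANONICAL_ORDER",
    "enumerate_combinations",
    "melamine_equivalent_levels",
    "adulterant_mass_fractions",
    "build_sample_table",
    "design_to_frame",
    "write_design_csv",
    "read_design_csv",
]

#: Canonical adulterant code order used for combo labels (e.g. "UGTM").
CANONICAL_ORDER = ("U", "G", "T", "M")

#: The three protein powder matrices of the study.
PROTEINS = ("whey", "beef", "pea")

#: Total sample mass after adulteration, grams.
TOTAL_MASS_G = 3.0

#: Melamine-equivalent dose levels 1..6 in %w/w; level 0 is the control.
LEVEL_PERCENTS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Concentration column names in design tables, keyed by adulterant code.
CONC_COLUMNS = {
    "M": "conc_melamine",
    "U": "conc_urea",
    "G": "conc_glycine",
    "T": "conc_taurine",
}


@dataclass(frozen=True)
class AdulterantSpec:
    """One adulterant compound and its elemental nitrogen mass fraction."""

    code: str
    name: str
    nitrogen_fraction: float

    def __post_init__(self) -> None:
        if self.code not in CANONICAL_ORDER:
            raise ValueError(f"unknown adulterant code {self.code!r}")
        if not 0.0 < self.nitrogen_fraction < 1.0:
            raise ValueError(
                f"nitrogen_fraction must lie in (0, 1), got {self.nitrogen_fraction}"
            )


#: Nitrogen mass fractions of the four adulterants (dimensionless).
DEFAULT_ADULTERANTS: dict[str, AdulterantSpec] = {
    "M": AdulterantSpec("M", "melamine", 0.6660),
    "U": AdulterantSpec("U", "urea", 0.4662),
    "G": AdulterantSpec("G", "glycine", 0.1865),
    "T": AdulterantSpec("T", "taurine", 0.1119),
}

#: Nitrogen fraction of melamine — the equivalence basis for dose levels.
MELAMINE_N = DEFAULT_ADULTERANTS["M"].nitrogen_fraction


@dataclass(frozen=True)
class MixtureCombo:
    """A non-empty subset of the adulterants, labelled in canonical order."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("combo must have at least one member")
        bad = set(self.members) - set(CANONICAL_ORDER)
        if bad:
            raise ValueError(f"unknown adulterant codes {sorted(bad)}")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate combo members")
        ordered = tuple(c for c in CANONICAL_ORDER if c in self.members)
        if ordered != self.members:
            object.__setattr__(self, "members", ordered)

    @property
    def label(self) -> str:
        return "".join(self.members)

    @classmethod
    def from_label(cls, label: str) -> "MixtureCombo":
        return cls(tuple(label))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SampleRecord:
    """One designed powder sample with its component mass fractions.

    ``mass_fractions`` maps component name (melamine/urea/glycine/taurine/
    protein) to g/100 g; the fractions close to 100 by construction.
    """

    sample_id: str
    protein: str
    combo: MixtureCombo | None
    level: int
    replicate: int
    mass_fractions: Mapping[str, float] = field(default_factory=dict)
    total_mass_g: float = TOTAL_MASS_G

    def __post_init__(self) -> None:
        if self.protein not in PROTEINS:
            raise ValueError(f"unknown protein {self.protein!r}")
        if not 0 <= self.level <= 6:
            raise ValueError(f"level must be 0..6, got {self.level}")
        if (self.level == 0) != (self.combo is None):
            raise ValueError("level 0 iff combo is None (control)")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


def enumerate_combinations() -> list[MixtureCombo]:
    """All 15 mixture combinations: singles, duals, triples and the quad.

    Every non-empty subset of {U, G, T, M}, in canonical order: by size,
    then lexicographically in the canonical code order. Deterministic.
    """
    combos: list[MixtureCombo] = []
    for size in range(1, len(CANONICAL_ORDER) + 1):
        for members in combinations(CANONICAL_ORDER, size):
            combos.append(MixtureCombo(members))
    return combos


def melamine_equivalent_levels() -> list[float]:
    """The six non-zero dose levels as total melamine-equivalent %w/w."""
    return list(LEVEL_PERCENTS)


def adulterant_mass_fractions(
    combo: MixtureCombo | str,
    level: int,
    specs: Mapping[str, AdulterantSpec] | None = None,
) -> dict[str, float]:
    """Per-adulterant mass fractions (g/100 g) for a combo at a dose level.

    The total added nitrogen equals ``level_percent × 0.6660`` (what pure
    melamine at that %w/w would carry) and is split equally among the
    combo's members, so ``mass_i = (N_tot / |combo|) / nitrogen_fraction_i``.

    Parameters
    ----------
    combo
        Mixture combination, or its label (e.g. ``"UGTM"``).
    level
        Dose level 1–6.
    specs
        Adulterant nitrogen fractions; defaults to the study compounds.

    Returns
    -------
    dict mapping adulterant code to mass fraction in g/100 g.
    """
    if isinstance(combo, str):
        combo = MixtureCombo.from_label(combo)
    if specs is None:
        specs = DEFAULT_ADULTERANTS
    if not 1 <= level <= 6:
        raise ValueError(f"level must be 1..6, got {level}")
    missing = [c for c in combo.members if c not in specs]
    if missing:
        raise KeyError(f"no AdulterantSpec for {missing}")
    n_total = LEVEL_PERCENTS[level - 1] * MELAMINE_N
    n_each = n_total / len(combo)
    return {c: n_each / specs[c].nitrogen_fraction for c in combo.members}


def _sample_id(protein: str, combo: MixtureCombo | None, level: int, replicate: int) -> str:
    label = combo.label if combo is not None else "CTRL"
    return f"{protein[:2].upper()}-{label}-L{level}-R{replicate}"


def build_sample_table(
    n_sample_replicates: int = 3,
    proteins: Iterable[str] = PROTEINS,
    specs: Mapping[str, AdulterantSpec] | None = None,
) -> list[SampleRecord]:
    """Enumerate every designed sample as a :class:`SampleRecord`.

    For each protein: (15 combos × 6 levels + 1 control) × replicates.
    With the study defaults that is 273 records per protein, 819 in total.
    Ordering is deterministic: protein, then control first, then combos in
    canonical order × level, then replicate.
    """
    if n_sample_replicates < 1:
        raise ValueError("need at least one replicate")
    records: list[SampleRecord] = []
    combos = enumerate_combinations()
    for protein in proteins:
        for rep in range(1, n_sample_replicates + 1):
            fractions = {spec.name: 0.0 for spec in DEFAULT_ADULTERANTS.values()}
            fractions["protein"] = 100.0
            records.append(
                SampleRecord(
                    sample_id=_sample_id(protein, None, 0, rep),
                    protein=protein,
                    combo=None,
                    level=0,
                    replicate=rep,
                    mass_fractions=fractions,
                )
            )
        for combo in combos:
            for level in range(1, 7):
                masses = adulterant_mass_fractions(combo, level, specs)
                for rep in range(1, n_sample_replicates + 1):
                    fractions = {
                        spec.name: masses.get(code, 0.0)
                        for code, spec in DEFAULT_ADULTERANTS.items()
                    }
                    fractions["protein"] = 100.0 - sum(masses.values())
                    records.append(
                        SampleRecord(
                            sample_id=_sample_id(protein, combo, level, rep),
                            protein=protein,
                            combo=combo,
                            level=level,
                            replicate=rep,
                            mass_fractions=fractions,
                        )
                    )
    return records


def design_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Design records as a tidy DataFrame with one row per sample."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "protein": r.protein,
                "combo": r.combo.label if r.combo is not None else "",
                "level": r.level,
                "replicate": r.replicate,
                "conc_melamine": r.mass_fractions.get("melamine", 0.0),
                "conc_urea": r.mass_fractions.get("urea", 0.0),
                "conc_glycine": r.mass_fractions.get("glycine", 0.0),
                "conc_taurine": r.mass_fractions.get("taurine", 0.0),
                "conc_protein": r.mass_fractions.get("protein", 100.0),
            }
        )
    return pd.DataFrame(rows)


def write_design_csv(records: list[SampleRecord], path: str | Path) -> None:
    design_to_frame(records).to_csv(path, index=False)


def read_design_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"combo": str}, keep_default_na=False)
    df["level"] = df["level"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df
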