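"""Titratable-group bookkeeping for a ligand and its carrier.

The effective pKa of a site in a protein environment is the water pKa of
the isolated group plus four perturbation terms (desolvation, hydrogen
bonding, electrostatic reorganization, Coulombic interactions), all in pH
units and consumed here as numeric inputs.  From effective pKas the module
evaluates Henderson--Hasselbalch protonated fractions, the net proton
exchange of a ligand between two environments (e.g. carrier-bound vs free
in water), isoelectric points, and their evolution along a trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

PERTURBATION_TERMS = ("desolvation", "hydrogen_bond", "reorganization", "coulombic")


@dataclass(frozen=True)
class TitratableGroup:
    """A one-proton titratable site.

    ``kind`` sets the charge convention: an acid is 0 protonated / -1
    deprotonated, a base +1 protonated / 0 deprotonated.  ``terms`` holds
    the environmental pKa perturbations in pH units (default 0 each).
    """

    label: str
    kind: str
    pKa_water: float
    terms: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("acid", "base"):
            raise ValueError("kind must be 'acid' or 'base'")
        unknown = set(self.terms) - set(PERTURBATION_TERMS)
        if unknown:
            raise ValueError(f"unknown perturbation terms {sorted(unknown)}")
        if not np.isfinite(self.effective_pka()):
            raise ValueError("effective pKa must be finite")

    def effective_pka(self) -> float:
        """Water pKa plus the sum of the perturbation terms."""
        return self.pKa_water + sum(self.terms.get(t, 0.0)
                                    for t in PERTURBATION_TERMS)


@dataclass
class TitratableSet:
    """A labelled collection of titratable groups (one physical context)."""

    groups: list
    context: str = ""

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique within a set")

    def by_label(self) -> dict:
        return {g.label: g for g in self.groups}

    def net_charge(self, pH: float) -> float:
        """Net charge at pH: protonated bases count +1, deprotonated acids -1."""
        q = 0.0
        for g in self.groups:
            theta = protonated_fraction(g.effective_pka(), pH)
            q += theta if g.kind == "base" else -(1.0 - theta)
        return q


def effective_pka(group: TitratableGroup) -> float:
    """Effective pKa of a group: pKa_water + desolvation + HB + RE + QQ."""
    return group.effective_pka()


def protonated_fraction(pKa: float, pH: float) -> float:
    """Henderson--Hasselbalch protonated fraction 1/(1+10^(pH-pKa))."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def net_proton_exchange(bound: TitratableSet, free: TitratableSet,
                        pH: float = 7.0) -> float:
    """Net protons gained by the ligand upon unbinding, at the given pH.

    Groups are matched by label; the returned value is
    ``sum_g theta(pKa_free) - theta(pKa_bound)`` -- positive when the free
    ligand is more protonated than the bound one.  The magnitude is the
    usual reported quantity; the sign encodes the direction of exchange.
    """
    b, f = bound.by_label(), free.by_label()
    unmatched = sorted(set(b) ^ set(f))
    if unmatched:
        raise ValueError(f"groups not present in both sets: {unmatched}")
    return float(sum(
        protonated_fraction(f[k].effective_pka(), pH)
        - protonated_fraction(b[k].effective_pka(), pH)
        for k in b))


def isoelectric_point(groups: TitratableSet, tol: float = 1e-6) -> float:
    """pH at which the set's net charge vanishes, by root bracketing on
    [0, 14] to |Q| < ``tol``.

    Requires at least one acid and one base (otherwise the net charge never
    changes sign and no isoelectric point exists).
    """
    kinds = {g.kind for g in groups.groups}
    if kinds != {"acid", "base"}:
        raise ValueError("no isoelectric point: need at least one acid and one base")
    q0, q1 = groups.net_charge(0.0), groups.net_charge(14.0)
    if q0 * q1 > 0:
        raise ValueError("no isoelectric point: net charge does not change "
                         "sign on pH 0..14")
    pI = brentq(groups.net_charge, 0.0, 14.0, xtol=1e-10)
    assert abs(groups.net_charge(pI)) < tol
    return float(pI)


def protonation_timeseries(table: pd.DataFrame, pH: float = 7.0) -> pd.DataFrame:
    """Track net proton exchange and pI along a trajectory of pKa values.

    ``table`` is long-format with columns (frame, label, kind, pKa); every
    frame is turned into a TitratableSet, the net proton exchange is
    evaluated against the first frame, and the pI is computed where the set
    admits one (NaN otherwise).  Frames missing any group of the first
    frame's schema are skipped and logged.
    """
    required = {"frame", "label", "kind", "pKa"}
    if table.empty:
        return pd.DataFrame(columns=["frame", "n_exchanged", "pI"])
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")

    def frame_set(sub, name):
        groups = [TitratableGroup(label=r.label, kind=r.kind, pKa_water=r.pKa)
                  for r in sub.itertuples()]
        return TitratableSet(groups, context=str(name))

    frames = sorted(table["frame"].unique())
    ref = frame_set(table[table["frame"] == frames[0]], frames[0])
    schema = set(ref.by_label())
    rows = []
    skipped = 0
    for fr in frames:
        sub = table[table["frame"] == fr]
        if set(sub["label"]) != schema:
            skipped += 1
            continue
        current = frame_set(sub, fr)
        n = net_proton_exchange(bound=ref, free=current, pH=pH)
        try:
            pI = isoelectric_point(current)
        except ValueError:
            pI = float("nan")
        rows.append({"frame": fr, "n_exchanged": n, "pI": pI})
    if skipped:
        logger.info("skipped %d frames with incomplete group schema", skipped)
    return pd.DataFrame(rows)


def s1p_reference_sets(bound_phosphate: float = 4.0, free_phosphate: float = 6.0,
                       bound_amine: float = 14.0, free_amine: float = 11.0
                       ) -> tuple[TitratableSet, TitratableSet]:
    """The ligand's titratable sets with the study's reference pKa values.

    The zwitterionic lysophospholipid carries two phosphate oxygens
    (acids; ~4 carrier-bound, ~6 free in water) and one amino nitrogen
    (base; ~14 bound, ~11 free).  Each phosphate oxygen is treated as an
    independent one-proton site.
    """
    bound = TitratableSet([
        TitratableGroup("phosphate_O1", "acid", bound_phosphate),
        TitratableGroup("phosphate_O2", "acid", bound_phosphate),
        TitratableGroup("amine_N", "base", bound_amine),
    ], context="carrier-bound")
    free = TitratableSet([
        TitratableGroup("phosphate_O1", "acid", free_phosphate),
        TitratableGroup("phosphate_O2", "acid", free_phosphate),
        TitratableGroup("amine_N", "base", free_amine),
    ], context="free in water")
    return bound, free
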