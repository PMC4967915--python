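"""Residue-wise force-distribution profiles from atom-pairwise forces.

Atom-pair force vectors between the ligand and the protein are vector-summed
per residue and per frame; the time average of the resulting magnitude, in
pN, is the residue's interaction-force profile value.  Profiles from
equilibrium and pulling runs can be thresholded and contrasted to flag the
residues that anchor the ligand or resist its extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .units import PN_PER_KJ_MOL_NM

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("frame", "atom_i", "atom_j", "fx", "fy", "fz")


@dataclass
class ResidueForceProfile:
    """Time-averaged ligand--residue force magnitudes in pN.

    Defined only for residues with at least one atom pair on record; frames
    in which a residue has no pair contribute a zero vector to its average.
    """

    values: pd.Series          # residue -> mean force, pN
    n_frames: int
    source: str = "equilibrium"

    def __post_init__(self):
        if (self.values < 0).any():
            raise ValueError("force magnitudes must be >= 0")


def aggregate_residue_profile(
    records: pd.DataFrame,
    ligand_atoms: Iterable[int],
    atom_to_residue: Mapping[int, object],
    source: str = "equilibrium",
) -> ResidueForceProfile:
    """Sum all ligand--residue atom-pair forces per frame and average.

    ``records`` stores, per row, the force on ``atom_i`` exerted by
    ``atom_j`` in kJ/mol/nm; rows may list the ligand atom on either side
    (the antisymmetric partner is implied).  Per frame, the force vectors on
    the ligand from each residue's atoms are vector-summed; the profile is
    the time average of the summed magnitude, converted to pN.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    lig = frozenset(int(a) for a in ligand_atoms)

    ai = records["atom_i"].to_numpy()
    aj = records["atom_j"].to_numpy()
    i_is_lig = np.isin(ai, list(lig))
    j_is_lig = np.isin(aj, list(lig))
    both = i_is_lig & j_is_lig
    neither = ~i_is_lig & ~j_is_lig
    if neither.any():
        # protein-protein rows are outside the ligand profile and ignored,
        # but every atom id must still be accounted for
        for a in np.unique(np.concatenate([ai[neither], aj[neither]])):
            if int(a) not in atom_to_residue:
                raise KeyError(f"atom id {int(a)} is neither a ligand atom nor "
                               "mapped to a protein residue")
    use = ~both & ~neither
    if not use.any():
        raise ValueError("no ligand-protein pairs in the records")

    prot = np.where(i_is_lig[use], aj[use], ai[use])
    unmapped = [int(a) for a in np.unique(prot) if a not in atom_to_residue]
    if unmapped:
        raise KeyError(f"atom id {unmapped[0]} has no residue mapping")

    fvec = records.loc[use, ["fx", "fy", "fz"]].to_numpy(dtype=float)
    # orient every vector as the force ON the ligand
    sign = np.where(i_is_lig[use], 1.0, -1.0)
    fvec = fvec * sign[:, None]

    frames = records.loc[use, "frame"].to_numpy()
    frame_ids = np.unique(records["frame"].to_numpy())
    n_frames = frame_ids.size
    span = int(frame_ids.max() - frame_ids.min()) + 1 if n_frames else 0
    if span != n_frames:
        logger.info("pairwise-force records have %d frame gaps", span - n_frames)

    residues = pd.Series([atom_to_residue[int(a)] for a in prot])
    df = pd.DataFrame({"frame": frames, "residue": residues.values,
                       "fx": fvec[:, 0], "fy": fvec[:, 1], "fz": fvec[:, 2]})
    sums = df.groupby(["residue", "frame"], sort=True)[["fx", "fy", "fz"]].sum()
    mags = np.sqrt((sums.to_numpy() ** 2).sum(axis=1))
    per_res = pd.Series(mags, index=sums.index.get_level_values("residue"))
    # frames with no pair for a residue count as zero force
    profile = per_res.groupby(level=0).sum() / n_frames * PN_PER_KJ_MOL_NM
    profile = profile.sort_index()
    return ResidueForceProfile(values=profile, n_frames=n_frames, source=source)


def select_key_residues(profile: ResidueForceProfile, threshold: float) -> list:
    """Residues whose mean force strictly exceeds ``threshold`` pN, sorted
    by decreasing force (ties broken by residue id for determinism)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    hits = profile.values[profile.values > threshold]
    order = sorted(hits.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [k for k, _ in order]


def diff_profiles(
    pulling: ResidueForceProfile,
    equilibrium: ResidueForceProfile,
    abs_floor: float = 40.0,
    ratio: float = 2.0,
) -> list:
    """Flag residues whose force is markedly increased under pulling.

    A residue is flagged when its pulling force exceeds ``abs_floor`` pN and
    the pulling/equilibrium ratio exceeds ``ratio`` (a residue absent from a
    profile counts as 0 pN; a zero equilibrium force gives an infinite
    ratio).  Returns residues sorted by decreasing pulling force.
    """
    universe = pulling.values.index.union(equilibrium.values.index)
    pull = pulling.values.reindex(universe, fill_value=0.0)
    eq = equilibrium.values.reindex(universe, fill_value=0.0)
    eqv = eq.to_numpy()
    pullv = pull.to_numpy()
    r = np.where(eqv > 0, pullv / np.where(eqv > 0, eqv, 1.0), np.inf)
    flagged = universe[(pullv > abs_floor) & (r > ratio)]
    return sorted(flagged, key=lambda k: (-pull[k], str(k)))


def write_profile_tsv(profile: ResidueForceProfile, path) -> None:
    out = pd.DataFrame({
        "residue": profile.values.index,
        "mean_force_pN": profile.values.to_numpy(),
        "n_frames": profile.n_frames,
    })
    out.to_csv(path, sep="\t", index=False)


def read_profile_tsv(path, source: str = "equilibrium") -> ResidueForceProfile:
    table = pd.read_csv(path, sep="\t")
    values = pd.Series(table["mean_force_pN"].to_numpy(),
                       index=table["residue"]).sort_index()
    return ResidueForceProfile(values=values,
                               n_frames=int(table["n_frames"].iloc[0]),
                               source=source)
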