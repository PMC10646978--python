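"""Synthetic stand-in for the wet lab.

Generates molecule libraries from a fragment-assembly grammar and simulates
plate-level HTS readings from a planted fragment-based structure-activity
relationship (SAR): the true log2 fold change of a molecule on each channel
is a sparse linear (+ optional pairwise interaction) function of its
fragment counters.  Replicate noise is lognormal on the fold scale
(Gaussian on log2), plates carry multiplicative lognormal factors that the
positive-control normalization must cancel, and a configurable fraction of
molecules is made non-viable.

All randomness flows through a named seed hierarchy: ``[seed, stream]``
with streams 0=library, 1=sar, 2=plates, 3=viability, so any sub-stream is
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from immunoloop import hts_data
from immunoloop.chemlib import CandidateLibrary, Molecule
from immunoloop.design_rules import fragment_counts
from immunoloop.hts_data import (CONTROL_POSITIVE, GOAL_CHANNELS,
                                 ModulationProfile, apply_viability_filter,
                                 merge_replicates, normalize_plate)


class SizeError(RuntimeError):
    """The assembly grammar cannot reach the requested library size."""


#: chainable SMILES units; concatenation of any sequence is a valid SMILES
ASSEMBLY_UNITS: tuple[str, ...] = (
    "C", "CC", "CCC", "O", "N", "S",
    "c1ccccc1", "c1ccncc1",
    "C(Cl)", "C(F)", "C(Br)",
    "C(=O)", "C(=O)N", "C(C)", "C(O)", "C(=O)C", "COC",
)

#: fragment counters known to vary under the assembly grammar; planted SARs
#: draw their supports from this pool
ACTIVE_FRAGMENT_POOL: tuple[str, ...] = (
    "fr_halogen", "fr_benzene", "fr_C_O", "fr_Ar_N", "fr_ether",
    "fr_NH1", "fr_ketone", "fr_amide", "fr_pyridine", "fr_alkyl_halide",
)


@dataclass
class SyntheticScreenConfig:
    library_size: int = 1000
    min_units: int = 2
    max_units: int = 6
    wells_per_plate: int = 60
    replicates: int = 2
    control_wells: int = 4
    control_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_wells < 1:
            raise ValueError("need >= 1 positive-control well per plate")


@dataclass
class PlantedSar:
    """Ground-truth SAR: per-channel sparse coefficients over fragment counters."""

    coefficients: dict          # (pathway, agonist) -> {fr_name: coef} (strong, recoverable)
    interactions: dict = field(default_factory=dict)  # channel -> [(fa, fb, coef)]
    background: dict = field(default_factory=dict)    # channel -> {fr_name: tiny coef}
    noise_sd: float = 0.1       # replicate log2-scale noise
    plate_effect_sd: float = 0.1
    nonviable_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.plate_effect_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0.0 <= self.nonviable_fraction <= 1.0:
            raise ValueError("nonviable_fraction must be in [0, 1]")

    @property
    def active_fragments(self) -> list[str]:
        """Strong planted fragments only — the recoverable ground truth."""
        seen: dict[str, None] = {}
        for coefs in self.coefficients.values():
            for name in coefs:
                seen.setdefault(name, None)
        for terms in self.interactions.values():
            for fa, fb, _ in terms:
                seen.setdefault(fa, None)
                seen.setdefault(fb, None)
        return list(seen)

    @property
    def all_fragments(self) -> list[str]:
        seen = {n: None for n in self.active_fragments}
        for coefs in self.background.values():
            for name in coefs:
                seen.setdefault(name, None)
        return list(seen)

    @classmethod
    def random(cls, seed: int = 0, n_active: int = 2,
               coef_range: tuple[float, float] = (0.4, 1.0),
               background_scale: float = 0.05,
               with_interactions: bool = False,
               pool: Optional[Sequence[str]] = None, **kwargs) -> "PlantedSar":
        """Seeded random sparse SAR over ``pool`` (default
        :data:`ACTIVE_FRAGMENT_POOL`).

        Each channel gets ``n_active`` strong coefficients (the recoverable
        signal) plus, when ``background_scale > 0``, tiny dense coefficients
        on the remaining pool fragments so oracle responses are effectively
        tie-free (mimicking the near-continuous spread of real fold changes).
        """
        pool = tuple(pool) if pool is not None else ACTIVE_FRAGMENT_POOL
        rng = np.random.default_rng([seed, 1])
        coefficients = {}
        background = {}
        for channel in GOAL_CHANNELS:
            picks = rng.choice(len(pool), size=n_active, replace=False)
            coefs = {}
            for j in picks:
                mag = rng.uniform(*coef_range)
                coefs[pool[j]] = float(mag * rng.choice([-1.0, 1.0]))
            coefficients[channel] = coefs
            if background_scale > 0:
                background[channel] = {
                    name: float(rng.uniform(-background_scale, background_scale))
                    for k, name in enumerate(pool) if k not in picks}
        interactions = {}
        if with_interactions:
            for channel in GOAL_CHANNELS:
                fa, fb = rng.choice(len(pool), size=2, replace=False)
                interactions[channel] = [(
                    pool[fa], pool[fb], float(rng.uniform(-0.3, 0.3)))]
        return cls(coefficients=coefficients, interactions=interactions,
                   background=background, seed=seed, **kwargs)


def generate_library(cfg: SyntheticScreenConfig,
                     parse_selfies: bool = True) -> CandidateLibrary:
    """Seeded, reproducible library of valid unique molecules.

    Molecules are random chains of :data:`ASSEMBLY_UNITS`, deduplicated by
    canonical SMILES.  ``parse_selfies=False`` skips SELFIES tokenization for
    speed when only fingerprint embeddings are needed downstream.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    seen: dict[str, None] = {}
    smiles_list: list[str] = []
    stalled = 0
    max_stall = 20_000  # consecutive attempts without a new unique molecule
    while len(smiles_list) < cfg.library_size:
        if stalled >= max_stall:
            raise SizeError(
                f"grammar stalled after {max_stall} consecutive non-unique "
                f"attempts (got {len(smiles_list)}/{cfg.library_size})")
        stalled += 1
        k = int(rng.integers(cfg.min_units, cfg.max_units + 1))
        units = rng.choice(len(ASSEMBLY_UNITS), size=k)
        smi = "".join(ASSEMBLY_UNITS[u] for u in units)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen[canon] = None
        smiles_list.append(canon)
        stalled = 0

    molecules = []
    for i, smi in enumerate(smiles_list):
        mol_id = f"SYN-{i:06d}"
        if parse_selfies:
            molecules.append(Molecule.from_smiles(mol_id, smi, vendor="synthetic"))
        else:
            molecules.append(Molecule(id=mol_id, smiles=smi, components=[smi],
                                      selfies_tokens=None, vendor="synthetic",
                                      selfies_error="selfies parsing skipped"))
    return CandidateLibrary(molecules=molecules)


def fragment_count_table(molecules: Sequence[Molecule],
                         fragments: Sequence[str]) -> np.ndarray:
    """(n, len(fragments)) counter matrix; computed once and reused."""
    return np.stack([fragment_counts(m, fragments) for m in molecules])


def oracle_response(m: Molecule, sar: PlantedSar,
                    channel: tuple[str, str]) -> float:
    """Noiseless true log2 fold change of one molecule on one channel."""
    coefs = dict(sar.background.get(channel, {}))
    coefs.update(sar.coefficients[channel])
    names = list(coefs)
    counts = fragment_counts(m, names)
    val = float(np.dot(counts, [coefs[n] for n in names]))
    for fa, fb, c in sar.interactions.get(channel, []):
        ca = fragment_counts(m, [fa])[0]
        cb = fragment_counts(m, [fb])[0]
        val += c * ca * cb
    return val


def oracle_log2_matrix(molecules: Sequence[Molecule], sar: PlantedSar,
                       count_table: Optional[pd.DataFrame] = None
                       ) -> pd.DataFrame:
    """True log2 fold changes, molecules x the six measured channels.

    ``count_table`` (ids x fragment codes) may be precomputed once per
    library and reused across SARs whose fragments it covers.
    """
    frags = sar.all_fragments
    if count_table is not None:
        counts = count_table.loc[[m.id for m in molecules], frags].to_numpy()
    else:
        counts = fragment_count_table(molecules, frags)
    col = {name: i for i, name in enumerate(frags)}
    data = {}
    for channel in GOAL_CHANNELS:
        coefs = dict(sar.background.get(channel, {}))
        coefs.update(sar.coefficients[channel])
        vec = np.zeros(len(frags))
        for name, c in coefs.items():
            vec[col[name]] = c
        vals = counts @ vec
        for fa, fb, c in sar.interactions.get(channel, []):
            vals = vals + c * counts[:, col[fa]] * counts[:, col[fb]]
        data[channel] = vals.astype(float)
    df = pd.DataFrame(data, index=[m.id for m in molecules])
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


def oracle_goal_targets(molecules: Sequence[Molecule], sar: PlantedSar,
                        goals=None) -> pd.DataFrame:
    """True signed log2 goal targets (larger = better), molecules x goals."""
    goals = goals if goals is not None else hts_data.all_goals()
    log2fc = oracle_log2_matrix(molecules, sar)
    out = {}
    for goal in goals:
        folds = np.stack([2.0 ** log2fc[(goal.pathway, a)].to_numpy()
                          for a in goal.agonists])
        base = folds.mean(axis=0)
        score = np.log2(base)
        out[goal.goal_id] = score if goal.direction == hts_data.ENHANCE else -score
    return pd.DataFrame(out, index=log2fc.index)


def simulate_plate_readings(molecules: Sequence[Molecule], sar: PlantedSar,
                            cfg: SyntheticScreenConfig,
                            rng: Optional[np.random.Generator] = None,
                            truth: Optional[pd.DataFrame] = None
                            ) -> pd.DataFrame:
    """Long-format raw readings for all molecules on the six goal channels.

    Per molecule x channel x replicate:
    ``raw = control_level * plate_factor * 2**(true_log2 + N(0, noise_sd^2))``;
    positive-control wells omit the SAR term.  Plate assignment is
    round-robin in molecule order; every plate carries its own lognormal
    factor per channel that normalization must cancel.  ``truth`` may supply
    a precomputed :func:`oracle_log2_matrix`.
    """
    if rng is None:
        rng = np.random.default_rng([sar.seed, 2])
    if truth is None:
        truth = oracle_log2_matrix(molecules, sar)
    mol_ids = np.array([m.id for m in molecules], dtype=object)
    n = len(molecules)
    n_plates = max(1, math.ceil(n / cfg.wells_per_plate))
    plate_of = np.arange(n) % n_plates
    frames = []
    for rep in range(cfg.replicates):
        for p in range(n_plates):
            plate_id = f"R{rep + 1}-P{p:04d}"
            member_idx = np.flatnonzero(plate_of == p)
            ids_p = mol_ids[member_idx]
            k = len(member_idx)
            for channel in GOAL_CHANNELS:
                pathway, agonist = channel
                factor = float(np.exp(rng.normal(0.0, sar.plate_effect_sd)))
                ctrl_raw = (cfg.control_level * factor
                            * 2.0 ** rng.normal(0.0, sar.noise_sd,
                                                cfg.control_wells))
                fc = 2.0 ** (truth[channel].to_numpy()[member_idx]
                             + rng.normal(0.0, sar.noise_sd, k))
                frames.append(pd.DataFrame({
                    "plate_id": plate_id,
                    "well": ([f"CTRL{w}" for w in range(cfg.control_wells)]
                             + [f"W{w}" for w in range(k)]),
                    "molecule_id": np.concatenate(
                        [np.full(cfg.control_wells, CONTROL_POSITIVE,
                                 dtype=object), ids_p]),
                    "channel": pathway,
                    "agonist": agonist,
                    "raw_value": np.concatenate(
                        [ctrl_raw, cfg.control_level * factor * fc]),
                }))
    return pd.concat(frames, ignore_index=True)


def simulate_viability(molecules: Sequence[Molecule], sar: PlantedSar,
                       rng: Optional[np.random.Generator] = None
                       ) -> dict[str, tuple[float, float]]:
    """Confluency score pairs; ~``nonviable_fraction`` of molecules get one
    mask score below the 0.70 threshold."""
    if rng is None:
        rng = np.random.default_rng([sar.seed, 3])
    scores = {}
    for m in molecules:
        bad = rng.random() < sar.nonviable_fraction
        hi = (float(rng.uniform(0.75, 1.0)), float(rng.uniform(0.75, 1.0)))
        if bad:
            low = float(rng.uniform(0.30, 0.6999))
            which = int(rng.integers(2))
            scores[m.id] = (low, hi[1]) if which == 0 else (hi[0], low)
        else:
            scores[m.id] = hi
    return scores


def run_screen(molecules: Sequence[Molecule], sar: PlantedSar,
               cfg: SyntheticScreenConfig,
               rng: Optional[np.random.Generator] = None,
               truth: Optional[pd.DataFrame] = None
               ) -> list[ModulationProfile]:
    """simulate -> normalize -> merge replicates -> viability, in one call."""
    readings = simulate_plate_readings(molecules, sar, cfg, rng=rng, truth=truth)
    folds = normalize_plate(readings)
    profiles = merge_replicates(folds, n_replicates=cfg.replicates)
    confluency = simulate_viability(molecules, sar, rng=rng)
    apply_viability_filter(profiles, confluency)
    return profiles
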