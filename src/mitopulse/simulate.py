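"""Generative model of three-channel pulse-SILAC evidence.

The simulator produces peptide-level L/M/H intensity tables with known
ground truth under the two experimental designs the package analyses:

* **pSILAC** — cells pre-labeled for ``pre_h`` hours (no drug), then labeled
  for ``drug_h`` more hours with drug or vehicle. The two conditions carry
  different labels (M vs H) and are pooled into one MS run per replicate;
  the H/M ratio reads out relative synthesis. A label swap across
  replicates cancels label-specific bias.
* **pulse-chase** — a ``pulse_h``-hour heavy pulse followed by a
  ``chase_h``-hour medium chase with drug or vehicle, one MS run per
  condition. Loss of the H cohort relative to pre-existing L protein reads
  out degradation of newly synthesized protein.

Kinetics: each protein follows first-order turnover
``dX/dt = s(t) - kd(t) * X`` with synthesis rate ``s`` (intensity units /
hour) and degradation rate ``kd`` (/hour). The drug multiplies synthesis by
``f`` (translational inhibition) and the degradation of newly made cohorts
by ``g >= 1`` (orphan-subunit destabilization). In the pulse-chase design
the pre-existing (assembled) pool always decays at the baseline ``kd``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .digest import DigestSpec, observable_peptides
from .proteins import ProteinRecord

logger = logging.getLogger(__name__)

EVIDENCE_COLUMNS = [
    "peptide_sequence",
    "protein_id",
    "replicate_id",
    "condition",
    "intensity_L",
    "intensity_M",
    "intensity_H",
]


@dataclass(frozen=True)
class TurnoverParams:
    """Per-protein kinetic parameters of the first-order turnover model.

    Parameters
    ----------
    s
        Synthesis rate, intensity units per hour.
    kd
        Degradation rate per hour; must be positive. The pre-drug steady
        state is ``A0 = s / kd``.
    f
        Drug multiplier on synthesis (``0`` = complete inhibition,
        ``1`` = no effect).
    g
        Drug multiplier on degradation of newly synthesized (and, in the
        pSILAC drug window, drug-exposed) cohorts; ``>= 1``.
    """

    s: float
    kd: float
    f: float = 1.0
    g: float = 1.0

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if self.f < 0:
            raise ValueError("f must be >= 0")
        if self.g < 1:
            raise ValueError("g must be >= 1")


@dataclass(frozen=True)
class PulseDesign:
    """Timing and replicate layout of a labeling experiment.

    ``design_kind`` selects between the 8 h + 16 h pSILAC design and the
    4 h pulse / 4 h chase design. ``swapped_replicates`` lists 1-based
    replicate indices whose M/H label assignment is exchanged (pSILAC) or
    recorded as swapped in metadata (pulse-chase, where channels have fixed
    roles).
    """

    design_kind: str = "psilac"
    pre_h: float = 8.0
    drug_h: float = 16.0
    pulse_h: float = 4.0
    chase_h: float = 4.0
    n_replicates: int = 2
    swapped_replicates: frozenset[int] = frozenset({2})
    conditions: tuple[str, ...] = ("CAP", "DMSO")

    def __post_init__(self) -> None:
        if self.design_kind not in ("psilac", "pulse_chase"):
            raise ValueError("design_kind must be 'psilac' or 'pulse_chase'")
        for name in ("pre_h", "drug_h", "pulse_h", "chase_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "swapped_replicates", frozenset(self.swapped_replicates))

    def cap_channel(self, replicate: int) -> str:
        """Channel carrying the drug condition's new cohort in a pSILAC replicate."""
        return "M" if replicate in self.swapped_replicates else "H"


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for simulated evidence.

    ``peptide_factor_sigma`` is the log-normal spread (natural-log scale) of
    peptide-specific ionization factors, shared across channels so that
    within-peptide ratios are preserved — the SILAC ratio principle.
    ``channel_noise_sigma`` is independent multiplicative log-normal noise
    per channel measurement. ``mixing_bias`` applies a global multiplicative
    factor per channel (L, M, H), emulating imperfect 1:1 mixing of the two
    labeled lysates. Dropout is channel-wise and logistic in log10
    intensity: ``P(drop | I) = expit(-slope * (log10 I - midpoint))``,
    monotone decreasing in intensity.
    """

    peptide_factor_sigma: float = 1.0
    channel_noise_sigma: float = 0.2
    mixing_bias: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dropout_midpoint: float = 4.0
    dropout_slope: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peptide_factor_sigma < 0 or self.channel_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if any(b <= 0 for b in self.mixing_bias):
            raise ValueError("mixing bias factors must be > 0")
        if self.dropout_slope < 0:
            raise ValueError("dropout_slope must be >= 0")

    def dropout_probability(self, intensity: np.ndarray) -> np.ndarray:
        """Logistic dropout probability as a function of intensity."""
        with np.errstate(divide="ignore"):
            log10_i = np.log10(np.maximum(intensity, np.finfo(float).tiny))
        return expit(-self.dropout_slope * (log10_i - self.dropout_midpoint))


NO_NOISE = NoiseModel(
    peptide_factor_sigma=0.0,
    channel_noise_sigma=0.0,
    mixing_bias=(1.0, 1.0, 1.0),
    dropout_midpoint=-np.inf,
    dropout_slope=0.0,
)
"""Noise-free model: unit peptide factors, no channel noise, no dropout."""


def channel_amounts_psilac(
    p: TurnoverParams, d: PulseDesign, drug_on: bool
) -> tuple[float, float]:
    """Closed-form (L, New) protein amounts at the end of a pSILAC time course.

    The pre-existing pool starts at steady state ``A0 = s/kd`` and decays; a
    "new" cohort accumulates during the ``pre_h`` label-only window at the
    baseline rates and during the ``drug_h`` window at the drug-modified
    rates (synthesis ``s*f``, degradation ``g*kd``). The new cohort is
    reported in channel H or M according to the replicate's label
    assignment; see :func:`generate_evidence`.
    """
    if d.design_kind != "psilac":
        raise ValueError("design_kind must be 'psilac'")
    t1, t2 = d.pre_h, d.drug_h
    f_eff = p.f if drug_on else 1.0
    kd_eff = p.g * p.kd if drug_on else p.kd
    a0 = p.s / p.kd
    pre_existing = a0 * np.exp(-p.kd * t1 - kd_eff * t2)
    new = (p.s / p.kd) * (1.0 - np.exp(-p.kd * t1)) * np.exp(-kd_eff * t2) + (
        p.s * f_eff / kd_eff
    ) * (1.0 - np.exp(-kd_eff * t2))
    return float(pre_existing), float(new)


def channel_amounts_chase(
    p: TurnoverParams, d: PulseDesign, drug_on: bool, proteasome_blocked: bool = False
) -> tuple[float, float, float]:
    """Closed-form (L, M, H) amounts at the end of a pulse-chase time course.

    H is the heavy pulse cohort (synthesized during ``pulse_h`` at baseline
    rates, chased at the drug-modified degradation rate); M is the chase
    cohort (synthesized during ``chase_h`` at drug-modified rates); L is the
    pre-existing pool, which always decays at the baseline ``kd`` —
    assembled proteins are not orphaned by the drug. With
    ``proteasome_blocked`` the degradation multiplier is suspended
    (``g -> 1``) while the synthesis effect persists, emulating MG132
    co-treatment.
    """
    if d.design_kind != "pulse_chase":
        raise ValueError("design_kind must be 'pulse_chase'")
    f_eff = p.f if drug_on else 1.0
    g_eff = 1.0 if (proteasome_blocked or not drug_on) else p.g
    kd_eff = g_eff * p.kd
    a0 = p.s / p.kd
    heavy = (p.s / p.kd) * (1.0 - np.exp(-p.kd * d.pulse_h)) * np.exp(-kd_eff * d.chase_h)
    medium = (p.s * f_eff / kd_eff) * (1.0 - np.exp(-kd_eff * d.chase_h))
    light = a0 * np.exp(-p.kd * (d.pulse_h + d.chase_h))
    return float(light), float(medium), float(heavy)


def _peptide_sequences(
    proteins: Sequence[ProteinRecord], digest_spec: DigestSpec
) -> dict[str, list[str]]:
    peptides: dict[str, list[str]] = {}
    for prot in proteins:
        obs = observable_peptides(prot, digest_spec)
        if not obs:
            logger.warning("protein %s has no observable peptides; skipped", prot.id)
            continue
        peptides[prot.id] = [pep.sequence for pep in obs]
    return peptides


def generate_evidence(
    proteins: Sequence[ProteinRecord],
    params: Mapping[str, TurnoverParams],
    design: PulseDesign,
    noise: NoiseModel,
    digest_spec: DigestSpec | None = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate a peptide-level SILAC evidence table.

    For every protein x replicate (x condition, in the pulse-chase design)
    the closed-form channel amounts are expanded to the protein's observable
    peptides: each peptide's intensity is the channel amount times a
    log-normal peptide ionization factor (shared across channels), an
    independent log-normal channel noise term, and the channel's mixing
    bias; each channel measurement is then dropped with a logistic
    probability in its log10 intensity. Rows with no surviving channel are
    removed. All randomness flows from ``noise.seed`` (or an explicit
    ``rng``), so equal seeds give identical tables.

    In the pSILAC design the two conditions share one run: channel L pools
    both dishes' pre-existing protein and the M/H channels carry the two
    conditions' new cohorts according to the replicate's label assignment
    (``condition`` is recorded as ``"pooled"``). In the pulse-chase design
    each condition is its own run with fixed channel roles.
    """
    if digest_spec is None:
        digest_spec = DigestSpec(proteases=frozenset({"lysc", "trypsin"}))
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    peptides = _peptide_sequences(proteins, digest_spec)
    missing = [p.id for p in proteins if p.id not in peptides and p.id in params]
    if missing:
        logger.info("%d protein(s) without observable peptides skipped", len(missing))

    rows: list[dict] = []
    bias = dict(zip("LMH", noise.mixing_bias))
    for prot in proteins:
        if prot.id not in peptides or prot.id not in params:
            continue
        p = params[prot.id]
        seqs = peptides[prot.id]
        # peptide factors are a property of the peptide: draw once per protein
        if noise.peptide_factor_sigma > 0:
            pep_factors = rng.lognormal(0.0, noise.peptide_factor_sigma, size=len(seqs))
        else:
            pep_factors = np.ones(len(seqs))
        for rep in range(1, design.n_replicates + 1):
            if design.design_kind == "psilac":
                l_cap, new_cap = channel_amounts_psilac(p, design, drug_on=True)
                l_ctl, new_ctl = channel_amounts_psilac(p, design, drug_on=False)
                cap_ch = design.cap_channel(rep)
                ctl_ch = "M" if cap_ch == "H" else "H"
                amounts = {"L": l_cap + l_ctl, cap_ch: new_cap, ctl_ch: new_ctl}
                rows.extend(
                    _peptide_rows(
                        seqs, pep_factors, amounts, prot.id, f"r{rep}", "pooled",
                        noise, bias, rng,
                    )
                )
            else:
                for condition in design.conditions:
                    drug_on = condition != "DMSO"
                    blocked = "MG132" in condition
                    light, medium, heavy = channel_amounts_chase(
                        p, design, drug_on=drug_on, proteasome_blocked=blocked
                    )
                    amounts = {"L": light, "M": medium, "H": heavy}
                    rows.extend(
                        _peptide_rows(
                            seqs, pep_factors, amounts, prot.id, f"r{rep}", condition,
                            noise, bias, rng,
                        )
                    )
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


def _peptide_rows(
    seqs: Sequence[str],
    pep_factors: np.ndarray,
    amounts: Mapping[str, float],
    protein_id: str,
    replicate_id: str,
    condition: str,
    noise: NoiseModel,
    bias: Mapping[str, float],
    rng: np.random.Generator,
) -> list[dict]:
    out = []
    for seq, factor in zip(seqs, pep_factors):
        row = {
            "peptide_sequence": seq,
            "protein_id": protein_id,
            "replicate_id": replicate_id,
            "condition": condition,
        }
        any_present = False
        for ch in "LMH":
            value = amounts[ch] * factor * bias[ch]
            if noise.channel_noise_sigma > 0:
                value *= rng.lognormal(0.0, noise.channel_noise_sigma)
            if noise.dropout_slope > 0 or np.isfinite(noise.dropout_midpoint):
                p_drop = float(noise.dropout_probability(np.asarray(value)))
                if rng.uniform() < p_drop:
                    value = np.nan
            if value == 0:
                value = np.nan
            row[f"intensity_{ch}"] = value
            if np.isfinite(value):
                any_present = True
        if any_present:
            out.append(row)
    return out


# ---------------------------------------------------------------------------
# Packaged default scenario
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# roughly human-proteome residue frequencies (K+R ~ 11% so tryptic peptides
# of observable length are common)
_AA_FREQ = np.array(
    [
        0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.044, 0.058, 0.100,
        0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.053, 0.060, 0.012, 0.027,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


def random_protein(
    rng: np.random.Generator,
    protein_id: str,
    length: Optional[int] = None,
    **kwargs,
) -> ProteinRecord:
    """A random protein with human-like residue composition."""
    if length is None:
        length = int(rng.integers(120, 600))
    seq = "".join(rng.choice(_AA, size=length, p=_AA_FREQ))
    return ProteinRecord(id=protein_id, sequence=seq, **kwargs)


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation scenario: proteins, truth, design, noise."""

    proteins: tuple[ProteinRecord, ...]
    params: Mapping[str, TurnoverParams]
    design: PulseDesign
    noise: NoiseModel
    digest_spec: DigestSpec
    localization: Optional[Mapping[str, str]] = None

    def annotation_table(self) -> pd.DataFrame:
        """Annotation rows for the simulated proteins (native schema)."""
        return pd.DataFrame(
            [
                {
                    "protein_id": p.id,
                    "gene": p.gene or p.id,
                    "encoding": p.encoding,
                    "complex": p.complex_,
                    "module": p.module or "",
                    "localization": (self.localization or {}).get(p.id, ""),
                }
                for p in self.proteins
            ]
        )

    def truth_table(self) -> pd.DataFrame:
        """Ground-truth sidecar table with per-protein (s, kd, f, g)."""
        return pd.DataFrame(
            [
                {"protein_id": pid, "s": p.s, "kd": p.kd, "f": p.f, "g": p.g}
                for pid, p in self.params.items()
            ]
        )

    def generate(self) -> pd.DataFrame:
        return generate_evidence(
            list(self.proteins), self.params, self.design, self.noise, self.digest_spec
        )


def default_psilac_scenario(
    seed: int,
    n_proteins: int = 1000,
    n_mt: int = 13,
    n_orphans: int = 50,
    mt_f: float = 0.05,
    orphan_f: float = 0.25,
    orphan_g: float = 1.0,
    channel_noise_sigma: float = 0.2,
    n_replicates: int = 2,
) -> Scenario:
    """The packaged pSILAC scenario with planted drug effects.

    ``n_mt`` mitochondrially-encoded proteins receive a strong synthesis
    block (``f = mt_f``); ``n_orphans`` nuclear proteins receive a milder
    planted effect (``f = orphan_f``, optionally ``g = orphan_g``); all
    remaining proteins are nulls (``f = g = 1``). Degradation rates are
    log-normal around a ~35 h half-life and steady-state abundances are
    log-normal around 1e6 intensity units, spanning the dynamic range over
    which intensity-dependent dropout acts.
    """
    rng = np.random.default_rng(seed)
    proteins = []
    params: dict[str, TurnoverParams] = {}
    localization: dict[str, str] = {}
    for i in range(n_proteins):
        if i < n_mt:
            pid, encoding = f"MT{i + 1:02d}", "mitochondrial"
            f_eff, g_eff = mt_f, 1.0
        elif i < n_mt + n_orphans:
            pid, encoding = f"ORPH{i - n_mt + 1:03d}", "nuclear"
            f_eff, g_eff = orphan_f, orphan_g
            localization[pid] = "mito"
        else:
            pid, encoding = f"NULL{i - n_mt - n_orphans + 1:04d}", "nuclear"
            f_eff, g_eff = 1.0, 1.0
            localization[pid] = "non-mito"
        prot = random_protein(rng, pid, encoding=encoding)
        kd = float(rng.lognormal(np.log(0.02), 0.6))
        a0 = float(rng.lognormal(np.log(1e6), 1.5))
        proteins.append(prot)
        params[pid] = TurnoverParams(s=a0 * kd, kd=kd, f=f_eff, g=g_eff)
    design = PulseDesign(
        design_kind="psilac",
        n_replicates=n_replicates,
        swapped_replicates=frozenset(range(2, n_replicates + 1, 2)),
    )
    noise = NoiseModel(channel_noise_sigma=channel_noise_sigma, seed=seed)
    spec = DigestSpec(proteases=frozenset({"lysc", "trypsin"}))
    return Scenario(tuple(proteins), params, design, noise, spec, localization)


def default_chase_scenario(
    seed: int,
    n_orphans: int = 20,
    n_stable: int = 40,
    orphan_g: float = 3.0,
    orphan_f: float = 0.3,
    channel_noise_sigma: float = 0.1,
    conditions: tuple[str, ...] = ("CAP", "DMSO"),
) -> Scenario:
    """The packaged pulse-chase scenario: orphan vs stable nuclear subunits.

    Orphans carry an accelerated degradation of the newly made cohorts
    (``g = orphan_g``) plus a partial synthesis block; stable proteins are
    unaffected by the drug.
    """
    rng = np.random.default_rng(seed)
    proteins = []
    params: dict[str, TurnoverParams] = {}
    for i in range(n_orphans + n_stable):
        orphan = i < n_orphans
        pid = f"ORPH{i + 1:03d}" if orphan else f"STAB{i - n_orphans + 1:03d}"
        prot = random_protein(rng, pid)
        kd = float(rng.lognormal(np.log(0.05), 0.4))
        a0 = float(rng.lognormal(np.log(1e6), 1.0))
        proteins.append(prot)
        params[pid] = TurnoverParams(
            s=a0 * kd,
            kd=kd,
            f=orphan_f if orphan else 1.0,
            g=orphan_g if orphan else 1.0,
        )
    design = PulseDesign(
        design_kind="pulse_chase", n_replicates=1, swapped_replicates=frozenset(),
        conditions=conditions,
    )
    noise = NoiseModel(
        channel_noise_sigma=channel_noise_sigma,
        peptide_factor_sigma=1.0,
        seed=seed,
    )
    spec = DigestSpec(proteases=frozenset({"lysc", "trypsin"}))
    return Scenario(tuple(proteins), params, design, noise, spec)
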