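"""Seeded generators for synthetic sequences, phosphosite sets and
turbidity curves.

The generators emulate the statistical structure of the experimental
system the analysis targets: ~110-residue diblock-ampholyte repeat units
with a basic (K/R-rich) N-terminal tract, a cluster of mitotic
S/T phosphosites (a tunable fraction carrying the minimal CDK1 S/T-P
context), and sigmoidal OD600-versus-concentration titrations with
additive Gaussian noise around a known saturation concentration.  All
outputs are pure functions of (config, seed).

Two phosphosite geometries matter:

* ``c_terminal_cluster`` — sites sit outside the basic tract, so mitotic
  hyperphosphorylation *adds* an acidic block after the basic one
  (blockiness-enhancing, Ki-67-like);
* ``within_basic_block`` — sites sit inside the basic tract, so
  phosphorylation cancels it (blockiness-reducing, NPM1-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .blockiness import compute_blc
from .charge import DEFAULT_MODEL, net_charge
from .phase import TurbidityCurve
from .sequences import AnnotatedSequence
from .variants import VariantRecord

#: neutral spacer alphabet: uncharged, no phospho-acceptors, no C/W/Y
SPACER_ALPHABET = "GAPNQ"

Placement = Literal["c_terminal_cluster", "within_basic_block", "uniform"]


@dataclass(frozen=True)
class TurbidityConfig:
    """Parameters of one simulated turbidity titration.

    Concentrations in µM, OD600 in absorbance units.  ``noise_sd`` is the
    standard deviation of additive Gaussian noise on OD600.
    """

    c_sat: float = 10.0
    hill: float = 4.0
    od_max: float = 1.0
    baseline: float = 0.02
    noise_sd: float = 0.05
    n_points: int = 12
    c_min: float = 0.5
    c_max: float = 200.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the target system's geometry: a 110-residue repeat
    unit, a ~35-residue basic block, nine mitotic phosphosites of which
    two thirds carry the S/T-P CDK1 consensus, and charge densities high
    enough that designated blocks (area > 20) form in the relevant state.
    """

    seed: int
    unit_length: int = 110
    n_pos_block: int = 35  # residues in the basic tract
    n_neg_block: int = 35  # residues in the acidic/phospho tract
    fraction_charged: float = 0.68  # charge density inside blocks
    acidic_background: int = 7  # acidic residues in the phospho region
    net_charge_target: int | None = None
    n_phosphosites: int = 9
    phospho_placement: Placement = "c_terminal_cluster"
    sp_motif_fraction: float = 2.0 / 3.0
    turbidity: TurbidityConfig = field(default_factory=TurbidityConfig)


def _check_feasible(cfg: GeneratorConfig) -> None:
    if cfg.n_pos_block + cfg.n_neg_block > cfg.unit_length:
        raise ValueError(
            f"blocks ({cfg.n_pos_block}+{cfg.n_neg_block}) exceed unit length "
            f"{cfg.unit_length}"
        )
    if cfg.n_phosphosites * 2 > max(cfg.n_pos_block, cfg.n_neg_block):
        raise ValueError(
            f"{cfg.n_phosphosites} phosphosites (each needing room for an S/T-P "
            f"dipeptide) do not fit in a {max(cfg.n_pos_block, cfg.n_neg_block)}-residue tract"
        )
    if not 0 <= cfg.sp_motif_fraction <= 1:
        raise ValueError("sp_motif_fraction must be in [0, 1]")


def gen_diblock_unit(cfg: GeneratorConfig) -> AnnotatedSequence:
    """Generate one annotated diblock-ampholyte repeat unit.

    The unit has a basic tract at the N terminus and a phosphosite set
    placed according to ``cfg.phospho_placement``; ``sp_motif_fraction``
    of the sites are immediately followed by Pro.  Identical config
    (including seed) yields identical output.
    """
    _check_feasible(cfg)
    rng = np.random.default_rng(cfg.seed)
    L = cfg.unit_length
    chars = list(rng.choice(list(SPACER_ALPHABET), size=L))

    # basic tract: K/R at fraction_charged density over the first n_pos_block
    n_pos_charges = round(cfg.fraction_charged * cfg.n_pos_block)
    tract = np.arange(cfg.n_pos_block)
    pos_slots = np.sort(rng.choice(tract, size=n_pos_charges, replace=False))
    for i in pos_slots:
        chars[i] = str(rng.choice(["K", "R"], p=[0.7, 0.3]))

    # phosphosite region
    if cfg.phospho_placement == "c_terminal_cluster":
        region = np.arange(L - cfg.n_neg_block, L)
    elif cfg.phospho_placement == "within_basic_block":
        region = tract
    elif cfg.phospho_placement == "uniform":
        region = np.arange(L)
    else:
        raise ValueError(f"unknown phospho placement {cfg.phospho_placement!r}")

    # evenly spaced site slots (each site keeps the next position free for
    # an optional Pro of the S/T-P consensus)
    free = [i for i in region if i + 1 < L and chars[i] not in "KRDE" and chars[i + 1] not in "KRDE"]
    if len(free) < cfg.n_phosphosites:
        raise ValueError("not enough uncharged slots for the requested phosphosites")
    idx = np.linspace(0, len(free) - 1, cfg.n_phosphosites).round().astype(int)
    site_slots = sorted({free[i] for i in idx})
    # even spacing can collide after rounding; backfill from unused slots
    spare = [s for s in free if s not in site_slots]
    while len(site_slots) < cfg.n_phosphosites and spare:
        site_slots.append(spare.pop(0))
    site_slots = sorted(site_slots)[: cfg.n_phosphosites]
    n_sp = round(cfg.sp_motif_fraction * cfg.n_phosphosites)
    for k, i in enumerate(site_slots):
        chars[i] = str(rng.choice(["S", "T"], p=[0.6, 0.4]))
        if k < n_sp:
            chars[i + 1] = "P"

    # acidic residues: a modest background inside a C-terminal phospho
    # region (so the mitotic acidic block clears the designation
    # threshold), or a dense stand-alone acidic block when the sites sit
    # inside the basic tract
    if cfg.phospho_placement == "within_basic_block":
        n_acid = round(cfg.fraction_charged * cfg.n_neg_block)
        acid_region = [
            i for i in range(L - cfg.n_neg_block, L) if chars[i] not in "KRDEST"
        ]
    else:
        n_acid = cfg.acidic_background
        acid_region = [
            i
            for i in region
            if chars[i] not in "KRDEP" and i not in site_slots and i - 1 not in site_slots
        ]
    if len(acid_region) < n_acid:
        raise ValueError("not enough room for acidic residues")
    for i in np.sort(rng.choice(acid_region, size=n_acid, replace=False)):
        chars[i] = str(rng.choice(["E", "D"], p=[0.75, 0.25]))

    seq = AnnotatedSequence(
        id=f"synthetic-unit-{cfg.phospho_placement}-seed{cfg.seed}",
        residues="".join(chars),
        phosphosites=frozenset(int(i) + 1 for i in site_slots),
        description=f"synthetic diblock repeat unit ({cfg.phospho_placement})",
    )
    if cfg.net_charge_target is not None:
        seq = _adjust_net_charge(seq, cfg.net_charge_target, rng)
    return seq


def _adjust_net_charge(
    seq: AnnotatedSequence, target: int, rng: np.random.Generator
) -> AnnotatedSequence:
    """Nudge the interphase net charge to ``target`` by converting neutral
    spacer residues (away from annotated sites) to K or E."""
    current = net_charge(seq, state="interphase")
    delta = target - current
    if delta == 0:
        return seq
    chars = list(seq.residues)
    eligible = [
        i
        for i in range(len(chars))
        if chars[i] in SPACER_ALPHABET
        and (i + 1) not in seq.phosphosites
        and i not in seq.phosphosites  # keep the residue after a site (Pro slot)
    ]
    if len(eligible) < abs(delta):
        raise ValueError(f"cannot reach net charge {target} from {current}")
    picks = rng.choice(eligible, size=abs(delta), replace=False)
    for i in picks:
        chars[i] = "K" if delta > 0 else "E"
    return seq.replace(residues="".join(chars))


# ---------------------------------------------------------------------------
# fixed-composition segregation gradient

def _gradient_arrangement(n_pairs: int, n_neutral: int, t: float, rng_spacer) -> str:
    """Charge arrangement at segregation level ``t`` in [0, 1].

    A diblock core of ``round(t * n_pairs)`` E/K pairs flanks a perfectly
    alternating remainder: t=0 is the fully alternating arrangement, t=1
    the fully segregated diblock.  Composition (E count, K count, neutral
    count) is independent of t; neutral residues are split between the
    two termini.
    """
    core = round(t * n_pairs)
    rest = n_pairs - core
    middle = "E" * core + "EK" * rest + "K" * core
    left = n_neutral // 2
    spacer = "".join(rng_spacer.choice(list(SPACER_ALPHABET), size=n_neutral))
    return spacer[:left] + middle + spacer[left:]


def gen_ensemble(
    cfg: GeneratorConfig,
    n: int,
    segregation_gradient: tuple[float, float] = (0.0, 1.0),
) -> list[VariantRecord]:
    """Fixed-composition sequences spanning an alternating-to-diblock gradient.

    Returns ``n`` variants whose charge arrangement moves monotonically
    from perfectly alternating to a fully segregated diblock while the
    residue composition stays identical, planting a monotone relation
    between arrangement and the segregation statistics.
    """
    if n < 3:
        raise ValueError("ensemble needs n >= 3")
    n_pairs = round(cfg.fraction_charged * cfg.unit_length / 2)
    n_neutral = cfg.unit_length - 2 * n_pairs
    # one fixed spacer RNG per member so composition is identical throughout
    ts = np.linspace(segregation_gradient[0], segregation_gradient[1], n)
    records = []
    for k, t in enumerate(ts):
        residues = _gradient_arrangement(n_pairs, n_neutral, float(t), np.random.default_rng(cfg.seed + 1))
        seq = AnnotatedSequence(
            id=f"gradient-{k}-t{t:.3f}", residues=residues,
            description="synthetic fixed-composition segregation gradient member",
        )
        records.append(
            VariantRecord(
                parent_id=f"gradient-seed{cfg.seed}",
                name=f"t={t:.3f}",
                sequence=seq,
                provenance={"rule": "gradient", "t": float(t), "seed": cfg.seed},
            )
        )
    return records


# ---------------------------------------------------------------------------
# turbidity curves

def gen_turbidity(
    cfg: GeneratorConfig,
    construct_id: str = "synthetic",
    replicate: str = "1",
) -> TurbidityCurve:
    """Simulate one OD600 titration from the log-logistic model plus noise.

    Concentrations are log-spaced; OD values are clamped at 0 after the
    noise is added.
    """
    t = cfg.turbidity
    if not t.c_min < t.c_sat < t.c_max:
        raise ValueError(
            f"c_sat {t.c_sat} must lie inside the concentration range "
            f"({t.c_min}, {t.c_max})"
        )
    rng = np.random.default_rng(cfg.seed)
    conc = np.geomspace(t.c_min, t.c_max, t.n_points)
    od = t.baseline + t.od_max / (1.0 + (t.c_sat / conc) ** t.hill)
    od = od + rng.normal(0.0, t.noise_sd, size=t.n_points)
    od = np.clip(od, 0.0, None)
    return TurbidityCurve(
        construct_id=construct_id, concentrations=conc, od600=od, replicate=replicate
    )


# ---------------------------------------------------------------------------
# planted blockiness -> C_sat study

@dataclass(frozen=True)
class StudyMember:
    variant: VariantRecord
    blc: float
    net_charge: int
    true_csat: float
    curve: TurbidityCurve


def gen_llps_study(
    cfg: GeneratorConfig,
    n: int = 18,
    log10_intercept: float = 2.0,
    log10_slope_per_blc: float = 0.03,
    csat_noise_sd_dex: float = 0.15,
) -> list[StudyMember]:
    """Generate a construct panel with a planted inverse blockiness-C_sat law.

    Each member is a 110-residue sequence whose diblock core size varies
    (so B_LC spans from no designated block to a strong diblock) and whose
    net charge is independently jittered over [-4, +5] by dispersed
    single-charge substitutions.  The true saturation concentration is
    drawn as

        log10 C_sat = intercept - slope * B_LC + N(0, noise_sd)

    and a noisy turbidity curve is simulated around it, closing the loop
    from sequence design to measured C_sat.
    """
    if n < 3:
        raise ValueError("study needs n >= 3")
    rng = np.random.default_rng(cfg.seed)
    members = []
    core_sizes = np.linspace(15, 35, n).round().astype(int)
    for k in range(n):
        s = int(core_sizes[k])
        # diblock core of s charges per sign, spacer fills the rest
        n_spacer = cfg.unit_length - 2 * s
        spacer = "".join(rng.choice(list(SPACER_ALPHABET), size=n_spacer))
        half = n_spacer // 3
        residues = spacer[:half] + "K" * s + spacer[half : 2 * half] + "E" * s + spacer[2 * half :]
        # net-charge jitter: dispersed single charges in the spacer
        jitter = int(rng.integers(-4, 6))
        chars = list(residues)
        neutral_slots = [i for i, c in enumerate(chars) if c in SPACER_ALPHABET]
        for i in rng.choice(neutral_slots, size=abs(jitter), replace=False):
            chars[i] = "K" if jitter > 0 else "E"
        seq = AnnotatedSequence(
            id=f"study-{k}-core{s}",
            residues="".join(chars),
            description="synthetic construct of the planted blockiness-C_sat study",
        )
        blc = compute_blc(seq, state="interphase")
        nc = net_charge(seq, state="interphase")
        log10_csat = (
            log10_intercept
            - log10_slope_per_blc * blc
            + rng.normal(0.0, csat_noise_sd_dex)
        )
        true_csat = float(10.0**log10_csat)
        tcfg = replace(
            cfg,
            seed=int(rng.integers(0, 2**31 - 1)),
            turbidity=replace(
                cfg.turbidity,
                c_sat=true_csat,
                c_min=true_csat / 30.0,
                c_max=true_csat * 30.0,
            ),
        )
        curve = gen_turbidity(tcfg, construct_id=seq.id)
        members.append(
            StudyMember(
                variant=VariantRecord(
                    parent_id=f"study-seed{cfg.seed}",
                    name=seq.id,
                    sequence=seq,
                    provenance={"rule": "llps-study", "core": s, "jitter": jitter},
                ),
                blc=blc,
                net_charge=nc,
                true_csat=true_csat,
                curve=curve,
            )
        )
    return members
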