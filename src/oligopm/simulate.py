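"""Synthetic-data generators with known ground truth.

Raw reader exports for the consumption study are not publicly deposited,
so every pipeline input is emulated here with a planted truth that the
consuming module must recover:

* kinetic plate sets — sigmoidal dye-reduction curves whose amplitude
  encodes a planted 0–5 consumption level per strain × substrate;
* the ``paper_like`` preset — a full strain panel whose planted substrate
  sets reproduce the qualitative design of the transporter study
  (wild-type superset of 207; a 59-substrate pair-only synergy set, 21 of
  them at level 4 versus 0 in single-transporter strains; a 14-substrate
  fraction with N-terminal Gly specific to non-Fot carriers; three weakly
  consumed peptides shared by every strain);
* promoter windows with motif consensus sites planted at known positions;
* qPCR Ct tables generated from known quantities and known amplification
  efficiency.

Every generator is deterministic given its seed, and noiseless output is
recovered exactly by the corresponding analysis module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import PlateLayout, build_default_catalog, universe
from .errors import ValidationError
from .motifs import ALPHABET, PWM, PromoterWindow
from .peptides import AA_ORDER, Peptide, Residue
from .qpcr import CT_COLUMNS
from .scoring import KineticCurve

#: Noiseless normalized AUC (percent of L-Gln) targeted by each level:
#: the center of the level's bin, with level 5 placed at 110 %.
LEVEL_TARGET_PCT = {0: 0.0, 1: 30.0, 2: 50.0, 3: 70.0, 4: 90.0, 5: 110.0}


@dataclass
class KineticSimConfig:
    """Parameters of the kinetic plate-set simulator.

    ``planted_levels`` is a strains × substrate-display-name integer
    DataFrame of ground-truth levels.  Signals follow
    ``baseline + amplitude(level) · logistic(t) + N(0, noise_sd)``,
    clipped at 0, sampled on ``timepoints`` points over [0, 72] h.
    The glutamine control uses ``gln_amplitude`` and the negative control
    amplitude 0, so a level's amplitude fraction equals its target percent.
    """

    planted_levels: pd.DataFrame
    baseline: float = 50.0
    gln_amplitude: float = 200.0
    noise_sd: float = 0.0
    midpoint_h: float = 24.0
    steepness_h: float = 4.0
    replicates: int = 2
    timepoints: int = 97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gln_amplitude <= 0:
            raise ValidationError("gln_amplitude must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.timepoints < 2:
            raise ValidationError("timepoints must be >= 2")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, 72.0, self.timepoints)


def _logistic(t: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - midpoint) / steepness))


def level_amplitude(level: int, cfg: KineticSimConfig) -> float:
    """Signal amplitude that lands a level at the center of its bin."""
    if level not in LEVEL_TARGET_PCT:
        raise ValidationError(f"level must be 0–5, got {level!r}")
    return cfg.gln_amplitude * LEVEL_TARGET_PCT[level] / 100.0


def simulate_curve(
    level: int,
    cfg: KineticSimConfig,
    rng: np.random.Generator,
    well: str = "A3",
    plate_id: str = "PM6",
    strain_id: str = "sim",
    replicate_id: str = "1",
    amplitude: float | None = None,
) -> KineticCurve:
    """One well's curve for a planted level (or explicit amplitude)."""
    amp = level_amplitude(level, cfg) if amplitude is None else amplitude
    t = cfg.times
    signal = cfg.baseline + amp * _logistic(t, cfg.midpoint_h, cfg.steepness_h)
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=t.size)
    signal = np.clip(signal, 0.0, None)
    return KineticCurve(
        times=t,
        signal=signal,
        well=well,
        plate_id=plate_id,
        strain_id=strain_id,
        replicate_id=replicate_id,
    )


def simulate_plate_set(
    cfg: KineticSimConfig, catalog: Sequence[PlateLayout]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format kinetics for every strain/plate/well/replicate, plus truth.

    Wells whose substrate is absent from ``cfg.planted_levels`` columns (or
    NA there) are omitted, emulating missing wells.  Returns
    ``(kinetics, truth_levels)``.
    """
    planted = cfg.planted_levels
    t = cfg.times
    log = _logistic(t, cfg.midpoint_h, cfg.steepness_h)
    rng = np.random.default_rng(cfg.seed)

    # amplitude per (plate, well) column layout, per strain
    well_meta: list[tuple[str, str, Peptide | None, str]] = []  # plate, well, pep, role
    for plate in catalog:
        well_meta.append((plate.plate_id, plate.negative_well, None, "neg"))
        well_meta.append((plate.plate_id, plate.positive_well, None, "pos"))
        for well, pep in plate.substrates():
            well_meta.append((plate.plate_id, well, pep, "substrate"))

    frames: list[pd.DataFrame] = []
    n_t = t.size
    for strain in planted.index:
        row = planted.loc[strain]
        amps: list[float] = []
        keep: list[tuple[str, str]] = []
        for plate_id, well, pep, role in well_meta:
            if role == "neg":
                amps.append(0.0)
            elif role == "pos":
                amps.append(cfg.gln_amplitude)
            else:
                name = pep.display_name  # type: ignore[union-attr]
                if name not in row.index or pd.isna(row[name]):
                    continue
                amps.append(level_amplitude(int(row[name]), cfg))
            keep.append((plate_id, well))
        amp_arr = np.asarray(amps)
        n_wells = amp_arr.size
        for rep in range(1, cfg.replicates + 1):
            signal = cfg.baseline + np.outer(amp_arr, log)
            if cfg.noise_sd > 0:
                signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
            signal = np.clip(signal, 0.0, None)
            frames.append(
                pd.DataFrame(
                    {
                        "strain_id": np.repeat(str(strain), n_wells * n_t),
                        "plate_id": np.repeat([p for p, _ in keep], n_t),
                        "well": np.repeat([w for _, w in keep], n_t),
                        "replicate_id": np.repeat(str(rep), n_wells * n_t),
                        "time_h": np.tile(t, n_wells),
                        "signal": signal.ravel(),
                    }
                )
            )
    kinetics = pd.concat(frames, ignore_index=True)
    return kinetics, planted.copy()


# ---------------------------------------------------------------------------
# The paper_like scenario preset

#: Strain identifiers of the preset panel, heatmap row order.
WILD_TYPE = "59A"
NONFOT_ONLY = "fot1fot2"
TRIPLE_DEL = "opt1opt2dal5"
PAIR_STRAIN = "PepKO-Fot1Fot2"
SINGLE_STRAINS = ("PepKO-Fot1", "PepKO-Fot2")
KNOCKOUT = "PepKO"
PRESET_STRAINS = (
    WILD_TYPE,
    TRIPLE_DEL,
    PAIR_STRAIN,
    "PepKO-FotX",
    "PepKO-Fot1",
    "PepKO-Fot2",
    "PepKO-Fot2Tm",
    "PepKO-Fot3",
    "PepKO-FotY",
    KNOCKOUT,
    NONFOT_ONLY,
)

#: Dipeptides weakly consumed by every strain, knockout included.
WEAK_UNIVERSAL = ("His–Pro", "Thr–Ser", "γ-Glu–Gly")


@dataclass
class Scenario:
    """A planted study design: simulator config plus named truth sets."""

    name: str
    config: KineticSimConfig
    catalog: list[PlateLayout]
    sets: dict[str, frozenset[Peptide]]
    strain_sets: dict[str, frozenset[Peptide]]
    pair_strain: str = PAIR_STRAIN
    single_strains: tuple[str, ...] = SINGLE_STRAINS
    reference_strain: str = WILD_TYPE
    having_strains: tuple[str, ...] = (NONFOT_ONLY,)
    lacking_strains: tuple[str, ...] = field(
        default_factory=lambda: tuple(
            s for s in PRESET_STRAINS
            if s not in (WILD_TYPE, NONFOT_ONLY, KNOCKOUT)
        )
    )


def paper_scenario(
    preset: str = "paper_like",
    noise_sd: float = 0.0,
    replicates: int = 2,
    seed: int = 1,
) -> Scenario:
    """Build the preset panel with planted substrate sets.

    The ``paper_like`` preset plants, on the default 284-substrate
    catalog: a wild type consuming 207 substrates (195 di + 12 tri); a
    191-substrate pair strain and a 189-substrate triple-deletion strain
    differing only in Gly–Leu and Lys–Trp at level 1; a 59-substrate
    synergy set consumed by the pair strains but by neither single (21 at
    level 4 versus 0); a 14-substrate fraction (12 di + 2 tri, all with
    N-terminal Gly) consumed only by strains retaining the non-Fot
    transporters; single-Fot ranges of 152/110/99; and three weakly
    consumed peptides shared by every strain.
    """
    if preset != "paper_like":
        raise ValidationError(f"unknown scenario preset {preset!r}")
    catalog = build_default_catalog()
    uni = universe(catalog)
    by_name = {p.display_name: p for p in uni}

    plain_di = [p for p in uni if len(p) == 2 and not p.is_modified]
    tri = [p for p in uni if len(p) == 3]
    weak3 = [by_name[n] for n in WEAK_UNIVERSAL]
    gly_leu = by_name["Gly–Leu"]
    lys_trp = by_name["Lys–Trp"]

    # 14-substrate non-Fot fraction: 12 Gly-X dipeptides + 2 Gly tripeptides
    glyx = [p for p in plain_di if p.n_terminal.code == "G" and p != gly_leu]
    tri_gly = [p for p in tri if p.n_terminal.code == "G"]
    g14 = glyx[:12] + tri_gly[:2]
    assert len(g14) == 14

    special2 = [gly_leu, lys_trp]
    wt_tri = tri_gly[:2] + [p for p in tri if p.n_terminal.code != "G"][:10]

    reserved = set(g14) | set(special2) | set(weak3)
    rest_di = [p for p in plain_di if p not in reserved]
    wt_extra_di = rest_di[:178]
    wt = set(g14) | set(special2) | set(weak3) | set(wt_extra_di) | set(wt_tri)
    assert len(wt) == 207

    x2 = wt_extra_di[-2:]  # consumed by the wild type only
    a_set = wt - set(g14) - set(special2) - set(x2)  # triple-deletion range
    assert len(a_set) == 189

    order = {p: i for i, p in enumerate(uni)}
    a_list = sorted(a_set, key=order.get)

    # 59-substrate synergy set: prefer Gly/Trp at either terminus and
    # Glu/Pro/Asp at the C-terminus, mirroring the planted composition bias
    cand = [p for p in a_list if p not in weak3]
    themed = [
        p
        for p in cand
        if p.n_terminal.code in "GW" or p.c_terminal.code in "GWEPD"
    ]
    s59 = themed[:59]
    if len(s59) < 59:
        extra = [p for p in cand if p not in set(s59)]
        s59 = s59 + extra[: 59 - len(s59)]
    s59_set = set(s59)
    s21 = s59[:21]  # level 4 in pair strains, 0 in singles

    pair_set = a_set | set(special2)
    p_pool = weak3 + [
        p for p in sorted(pair_set - s59_set, key=order.get) if p not in weak3
    ]
    assert len(p_pool) == 132
    fot1 = set(p_pool[:120])
    fot2 = set(p_pool[:103]) | set(p_pool[120:])
    assert fot1 | fot2 == set(p_pool)

    leftovers = [p for p in uni if p not in wt and not p.is_modified]
    fotx = set(p_pool[:122]) | set(leftovers[:30])
    fot3 = set(p_pool[:83]) | set(leftovers[:27])
    foty = set(p_pool[:72]) | set(leftovers[:27])
    assert (len(fotx), len(fot3), len(foty)) == (152, 110, 99)

    strain_sets: dict[str, frozenset[Peptide]] = {
        WILD_TYPE: frozenset(wt),
        TRIPLE_DEL: frozenset(a_set),
        PAIR_STRAIN: frozenset(pair_set),
        "PepKO-FotX": frozenset(fotx),
        "PepKO-Fot1": frozenset(fot1),
        "PepKO-Fot2": frozenset(fot2),
        "PepKO-Fot2Tm": frozenset(fot2),
        "PepKO-Fot3": frozenset(fot3),
        "PepKO-FotY": frozenset(foty),
        KNOCKOUT: frozenset(weak3),
        NONFOT_ONLY: frozenset(g14) | frozenset(weak3),
    }

    # planted levels: random 1–5 for consumed cells, then pinned values
    names = [p.display_name for p in uni]
    rng = np.random.default_rng(seed)
    levels = pd.DataFrame(
        0, index=pd.Index(PRESET_STRAINS, name="strain_id"), columns=names, dtype=int
    )
    for strain in PRESET_STRAINS:
        draw = rng.choice([1, 2, 3, 4, 5], size=len(uni), p=[0.25, 0.25, 0.2, 0.2, 0.1])
        mask = np.array([p in strain_sets[strain] for p in uni])
        col = np.where(mask, draw, 0)
        levels.loc[strain] = col
    s38_draw = rng.integers(1, 4, size=len(s59) - 21)  # levels 1–3
    for strain in (TRIPLE_DEL, PAIR_STRAIN):
        for p in s21:
            levels.loc[strain, p.display_name] = 4
        for p, lev in zip(s59[21:], s38_draw):
            levels.loc[strain, p.display_name] = int(lev)
    for p in weak3:
        levels[p.display_name] = 1  # weak and universal
    for p in special2:
        levels.loc[PAIR_STRAIN, p.display_name] = 1

    cfg = KineticSimConfig(
        planted_levels=levels,
        noise_sd=noise_sd,
        replicates=replicates,
        seed=seed,
    )
    return Scenario(
        name=preset,
        config=cfg,
        catalog=catalog,
        sets={
            "wild_type": frozenset(wt),
            "synergy_59": frozenset(s59_set),
            "synergy_level4_21": frozenset(s21),
            "nonfot_14": frozenset(g14),
            "weak_universal": frozenset(weak3),
            "wild_type_only": frozenset(x2),
        },
        strain_sets=strain_sets,
    )


# ---------------------------------------------------------------------------
# Promoter and qPCR simulators

def simulate_promoters(
    n_genes: int,
    planted: Mapping[str, tuple[PWM, int]],
    gc: float = 0.5,
    length: int = 500,
    seed: int = 0,
) -> tuple[list[PromoterWindow], pd.DataFrame]:
    """I.i.d.-background promoter windows with planted consensus sites.

    ``planted`` maps gene ids (``gene1`` … ``gene{n}``) to (motif,
    1-based position).  Returns the windows and a truth table with the
    planted motif id and position per gene.
    """
    p_gc = gc / 2.0
    probs = [(1 - gc) / 2, p_gc, p_gc, (1 - gc) / 2]  # A C G T
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1}" for i in range(n_genes)]
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValidationError(f"planted sites for unknown genes {sorted(unknown)}")
    windows = []
    truth_rows = []
    for gene in genes:
        seq = "".join(rng.choice(list(ALPHABET), size=length, p=probs))
        if gene in planted:
            pwm, pos = planted[gene]
            if not (1 <= pos <= length - pwm.width + 1):
                raise ValidationError(
                    f"planted position {pos} leaves no room for motif "
                    f"{pwm.motif_id!r} (width {pwm.width}) in {length} bp"
                )
            seq = seq[: pos - 1] + pwm.consensus + seq[pos - 1 + pwm.width :]
            truth_rows.append(
                {"gene_id": gene, "motif_id": pwm.motif_id, "start": pos}
            )
        windows.append(PromoterWindow(gene_id=gene, sequence=seq))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "motif_id", "start"])
    return windows, truth


def write_promoter_fasta(windows: Sequence[PromoterWindow], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in windows:
            fh.write(f">{w.gene_id}\n")
            for i in range(0, len(w.sequence), 60):
                fh.write(w.sequence[i : i + 60] + "\n")


def demo_pwms() -> list[PWM]:
    """Two synthetic demonstration motifs (toy stand-ins, not curated
    database matrices): a GATA-core activator site and a longer
    repressor-like site."""
    gata = PWM.from_frequencies(
        "GLN3_demo",
        np.array(
            [
                [0.05, 0.05, 0.85, 0.05],
                [0.90, 0.03, 0.03, 0.04],
                [0.04, 0.04, 0.04, 0.88],
                [0.90, 0.03, 0.03, 0.04],
                [0.80, 0.07, 0.06, 0.07],
                [0.10, 0.10, 0.70, 0.10],
            ]
        ),
    )
    rep = PWM.from_consensus("CUP9_demo", "TGATTGCTA", match=2.0, mismatch=-1.0)
    return [gata, rep]


def simulate_qpcr(
    planted_quantities: Mapping[str, Mapping[str, float]],
    efficiency: float = 1.0,
    noise_sd_ct: float = 0.0,
    dilution_log10: Sequence[float] = (0.0, -1.0, -2.0, -3.0, -4.0),
    replicates: int = 3,
    intercept: float = 34.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table for standards plus unknowns from planted quantities.

    ``planted_quantities`` maps sample id → {gene id → quantity in the
    standards' arbitrary units}.  Ct values follow
    ``intercept + slope · log10(q) + N(0, noise_sd_ct)`` with
    ``slope = −1 / log10(1 + efficiency)``.
    """
    if not (0.5 < efficiency <= 1.2):
        raise ValidationError("efficiency must lie in (0.5, 1.2]")
    if len(dilution_log10) < 3:
        raise ValidationError("need at least 3 dilution points")
    slope = -1.0 / np.log10(1.0 + efficiency)
    rng = np.random.default_rng(seed)
    genes = sorted({g for qs in planted_quantities.values() for g in qs})
    rows = []
    for gene in genes:
        for lq in dilution_log10:
            for rep in range(1, replicates + 1):
                ct = intercept + slope * lq
                if noise_sd_ct > 0:
                    ct += rng.normal(0.0, noise_sd_ct)
                rows.append(
                    {
                        "sample_id": f"std_{gene}",
                        "gene_id": gene,
                        "role": "standard",
                        "log10_quantity": lq,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
    truth_rows = []
    for sample, qs in planted_quantities.items():
        for gene, q in qs.items():
            if q <= 0:
                raise ValidationError("planted quantities must be positive")
            for rep in range(1, replicates + 1):
                ct = intercept + slope * np.log10(q)
                if noise_sd_ct > 0:
                    ct += rng.normal(0.0, noise_sd_ct)
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": gene,
                        "role": "unknown",
                        "log10_quantity": np.nan,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
            truth_rows.append({"sample_id": sample, "gene_id": gene, "quantity": q})
    table = pd.DataFrame(rows, columns=list(CT_COLUMNS))
    truth = pd.DataFrame(truth_rows)
    return table, truth


# ---------------------------------------------------------------------------
# Composition-analysis helpers

def random_peptides(
    n: int, length: int = 3, seed: int = 0, modifier_fraction: float = 0.0
) -> list[Peptide]:
    """*n* distinct random peptides of the given length."""
    rng = np.random.default_rng(seed)
    out: list[Peptide] = []
    seen: set[Peptide] = set()
    max_unique = 20**length
    if n > max_unique:
        raise ValidationError(f"cannot draw {n} distinct peptides of length {length}")
    while len(out) < n:
        codes = rng.choice(list(AA_ORDER), size=length)
        p = Peptide(tuple(Residue(str(c)) for c in codes))
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def sample_enriched_set(
    background: Sequence[Peptide],
    code: str,
    position: str,
    fold: float,
    n: int,
    seed: int = 0,
) -> list[Peptide]:
    """Sample *n* peptides so that *code*'s frequency at *position* is
    ``fold`` × its background frequency (up to count rounding)."""
    def has(p: Peptide) -> bool:
        if position == "N_terminal":
            return p.n_terminal.code == code
        if position == "C_terminal":
            return p.c_terminal.code == code
        raise ValidationError(f"unsupported position {position!r}")

    matching = [p for p in background if has(p)]
    rest = [p for p in background if not has(p)]
    bg_freq = len(matching) / len(background)
    k = round(fold * bg_freq * n)
    if k > len(matching) or n - k > len(rest):
        raise ValidationError(
            f"background too small for {fold}x enrichment of {code} at {position}"
        )
    rng = np.random.default_rng(seed)
    pick_m = rng.choice(len(matching), size=k, replace=False)
    pick_r = rng.choice(len(rest), size=n - k, replace=False)
    return [matching[i] for i in pick_m] + [rest[i] for i in pick_r]
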