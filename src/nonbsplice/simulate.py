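"""Synthetic genomes, exon models and skipping labels with known ground
truth.

Each simulated entry is a three-exon gene on its own contig: the middle
(cassette) exon is flanked by an upstream and a downstream intron whose
lengths are drawn from a truncated log-normal (median ~1.5 kb, heavy right
tail).  Motif instances are planted into the introns at configured rates
per (structure, region, strand); instances are drawn from the class
grammars with short "guard" bases that stop the scanners from extending a
match beyond the planted coordinates.  Every intron is re-scanned after
planting and redrawn until each planted instance is recovered at its exact
coordinates, so planted recall is 100 % by construction; accidental
background occurrences elsewhere in the intron are kept and reported.

The skipping label of each entry is drawn from a logistic model over the
12-column design vector of the *realized* intron content (planted plus
accidental occurrences, after the polypyrimidine-tract and cross-class
filters — i.e. exactly the counts the analysis pipeline will recompute)
plus, optionally, the maximum G-run length of upstream template-strand G4.
With ``confound_intron_length`` set, planting rates scale linearly with
intron length, so occurrence counts correlate with length and the
partial-correlation adjustment is genuinely exercised.

Motif-instance construction notes (all deliberate, to keep classes from
colliding inside a planted site): G4 loops and guards are pyrimidines with
at most two consecutive C; triplex arms and spacers are purines with at
most two consecutive G; Z-DNA instances are GT- or AC-alternating tracts
(the dominant genomic Z-motif) capped at 19 nt so a tract can never double
as a direct repeat.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotation import Region, profile_intron
from .scan import (
    MotifHit,
    ScanParams,
    Strand,
    StructureClass,
    scan_all,
)
from .seq import decode, encode, revcomp
from .stats import DESIGN_COLUMNS

__all__ = [
    "SimulationConfig",
    "PlantedMotif",
    "TruthEntry",
    "TruthTable",
    "SimulationError",
    "generate_background_sequence",
    "plant_motif",
    "simulate_dataset",
    "simulate_truth",
]

_STRUCTURES = ("g4", "cruciform", "triplex", "slipped", "zdna")
_MARGIN = 60          # nt kept free of plants at each intron end
_MIN_GAP = 60         # nt between planted cores
_BACKGROUND_BASES = np.array([0, 1, 2, 3], dtype=np.uint8)  # A C G T


class SimulationError(RuntimeError):
    pass


def _default_plant_rates() -> dict:
    """Expected planted occurrences per intron, keyed by
    (structure, region, strand); strand is None except for G4."""
    rates = {}
    for region in ("upstream", "downstream"):
        rates[("g4", region, "template")] = 0.10
        rates[("g4", region, "nontemplate")] = 0.10
        rates[("cruciform", region, None)] = 0.03
        rates[("triplex", region, None)] = 0.15
        rates[("slipped", region, None)] = 0.08
        rates[("zdna", region, None)] = 0.05
    return rates


def _default_beta() -> pd.Series:
    """Null generative model at the human background skipping rate 0.148."""
    beta = pd.Series(0.0, index=["intercept"] + list(DESIGN_COLUMNS))
    beta["intercept"] = math.log(0.148 / (1.0 - 0.148))
    return beta


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic dataset.

    ``true_beta`` is a 13-vector (intercept followed by the 12 design
    columns in :data:`nonbsplice.stats.DESIGN_COLUMNS` order) on the logit
    scale; the default is the null model whose intercept reproduces a
    background skipping probability of 0.148.  ``g_run_effect`` adds
    ``g_run_effect * (maximum upstream template-strand G-run length)`` to
    the linear predictor.  With ``confound_intron_length`` the per-intron
    planting rate is ``rate * length / intron_length_median``.
    """

    n_entries: int = 20_000
    intron_length_median: float = 1500.0
    intron_length_sigma: float = 0.7
    intron_length_min: int = 200
    intron_length_max: int = 10_000
    gc_content: float = 0.42
    plant_rates: dict = field(default_factory=_default_plant_rates)
    g_run_length_range: tuple[int, int] = (3, 6)
    true_beta: pd.Series = field(default_factory=_default_beta)
    g_run_effect: float = 0.0
    confound_intron_length: bool = False
    exon_length_range: tuple[int, int] = (90, 180)
    pad: int = 30
    seed: int = 0
    scan_params: ScanParams = field(default_factory=ScanParams)
    max_intron_attempts: int = 50

    def __post_init__(self) -> None:
        if self.n_entries <= 0:
            raise ValueError("n_entries must be positive")
        if not 0.0 <= self.gc_content < 1.0:
            raise ValueError("gc_content must lie in [0, 1)")
        for key, rate in self.plant_rates.items():
            if rate < 0:
                raise ValueError(f"negative plant rate for {key}")
            structure, region, strand = key
            if structure not in _STRUCTURES or region not in (
                "upstream", "downstream",
            ):
                raise ValueError(f"unknown plant-rate key {key}")
            if (structure == "g4") != (strand in ("template", "nontemplate")):
                raise ValueError(f"bad strand in plant-rate key {key}")
        beta = pd.Series(self.true_beta, dtype=float)
        expected = ["intercept"] + list(DESIGN_COLUMNS)
        if list(beta.index) == list(range(13)):
            beta.index = expected
        if list(beta.index) != expected:
            raise ValueError("true_beta must be indexed intercept + 12 design columns")
        self.true_beta = beta
        lo, hi = self.g_run_length_range
        if not self.scan_params.g4_min_run <= lo <= hi:
            raise ValueError("invalid g_run_length_range")


@dataclass(frozen=True)
class PlantedMotif:
    structure: str
    region: str
    strand: Optional[str]  # template / nontemplate for G4, else None
    start: int             # intron coordinates, transcription orientation
    end: int
    g_run_length: int = 0


@dataclass
class TruthEntry:
    entry_id: str
    orientation: str
    upstream_length: int
    downstream_length: int
    planted: list[PlantedMotif]
    design: dict[str, float]
    n_accidental: int
    linear_predictor: float
    probability: float
    label: str


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset."""

    entries: list[TruthEntry]
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {
                "entry_id": e.entry_id,
                "orientation": e.orientation,
                "upstream_length": e.upstream_length,
                "downstream_length": e.downstream_length,
                "n_planted": len(e.planted),
                "n_accidental": e.n_accidental,
                "linear_predictor": e.linear_predictor,
                "probability": e.probability,
                "label": e.label,
            }
            row.update(e.design)
            rows.append(row)
        return pd.DataFrame(rows)

    def planted_frame(self) -> pd.DataFrame:
        rows = [
            {
                "entry_id": e.entry_id,
                "structure": p.structure,
                "region": p.region,
                "strand": p.strand or ".",
                "start": p.start,
                "end": p.end,
                "g_run_length": p.g_run_length,
            }
            for e in self.entries
            for p in e.planted
        ]
        return pd.DataFrame(
            rows,
            columns=["entry_id", "structure", "region", "strand", "start",
                     "end", "g_run_length"],
        )

    def design_matrix(self) -> tuple[pd.DataFrame, pd.Series]:
        X = pd.DataFrame(
            [e.design for e in self.entries],
            index=[e.entry_id for e in self.entries],
        )[list(DESIGN_COLUMNS)]
        y = pd.Series(
            [1 if e.label == "SKIPPED" else 0 for e in self.entries],
            index=X.index,
            name="skipped",
        )
        return X, y


# ---------------------------------------------------------------------------
# background sequence

def _background_codes(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BACKGROUND_BASES[rng.choice(4, size=length, p=p)]


def generate_background_sequence(
    length: int,
    gc: float,
    rng: np.random.Generator,
    exclusion_zones: Optional[list[tuple[int, int]]] = None,
    params: Optional[ScanParams] = None,
    max_attempts: int = 1000,
) -> str:
    """An i.i.d. background sequence at the target GC content.

    When ``exclusion_zones`` is given (intervals where motifs will later be
    planted), the draw is rejected and repeated until no scanner class hits
    within +/- 50 nt of any zone; after ``max_attempts`` failures a
    :class:`SimulationError` suggests lowering the GC content.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    params = params or ScanParams()
    for _ in range(max_attempts):
        seq = decode(_background_codes(length, gc, rng))
        if not exclusion_zones:
            return seq
        zones = [
            (max(0, s - 50), min(length, e + 50)) for s, e in exclusion_zones
        ]
        hits = scan_all(seq, params)
        clean = True
        for cls_hits in hits.values():
            for h in cls_hits:
                if any(h.start < ze and zs < h.end for zs, ze in zones):
                    clean = False
                    break
            if not clean:
                break
        if clean:
            return seq
    raise SimulationError(
        f"no clean background of length {length} after {max_attempts} "
        f"attempts; consider a lower GC content than {gc}"
    )


# ---------------------------------------------------------------------------
# motif instance construction

def _constrained_string(
    rng: np.random.Generator, length: int, common: str, rare: str, max_rare_run: int = 2
) -> str:
    """Random string over two bases with at most ``max_rare_run``
    consecutive copies of ``rare``."""
    out = []
    run = 0
    for _ in range(length):
        if run >= max_rare_run:
            ch = common
        else:
            ch = rare if rng.random() < 0.4 else common
        run = run + 1 if ch == rare else 0
        out.append(ch)
    return "".join(out)


def _build_g4(rng: np.random.Generator, params: ScanParams, max_run: int):
    nruns = params.g4_min_runs
    which = int(rng.integers(nruns))
    lengths = [
        max_run if i == which else int(rng.integers(params.g4_min_run, max_run + 1))
        for i in range(nruns)
    ]
    loop_hi = min(params.g4_loop_max, 7)
    parts = []
    for i, L in enumerate(lengths):
        if i:
            loop_len = int(rng.integers(params.g4_loop_min, loop_hi + 1))
            parts.append(_constrained_string(rng, loop_len, "T", "C"))
        parts.append("G" * L)
    core = "".join(parts)
    guard = 12  # blocks run extension and chaining into flanking background
    lg = _constrained_string(rng, guard, "T", "C")
    rg = _constrained_string(rng, guard, "T", "C")
    return core, lg, rg, {"max_run": max_run}


def _build_cruciform(rng: np.random.Generator, params: ScanParams):
    arm = int(rng.integers(params.ir_min_arm, params.ir_min_arm + 5))
    spacer = int(rng.integers(0, params.ir_max_spacer + 1))
    left = decode(_BACKGROUND_BASES[rng.integers(0, 4, size=arm)])
    mid = decode(_BACKGROUND_BASES[rng.integers(0, 4, size=spacer)])
    core = left + mid + revcomp(left)
    return core, "A", "A", {}


def _build_triplex(rng: np.random.Generator, params: ScanParams):
    arm = int(rng.integers(params.mr_min_arm, params.mr_min_arm + 4))
    spacer = int(rng.integers(0, min(params.mr_max_spacer, 8) + 1))
    left = _constrained_string(rng, arm, "A", "G")
    mid = _constrained_string(rng, spacer, "A", "G")
    core = left + mid + left[::-1]
    return core, "T", "C", {}


def _build_slipped(rng: np.random.Generator, params: ScanParams):
    unit_len = int(rng.integers(params.dr_min_unit, params.dr_min_unit + 5))
    spacer = int(rng.integers(0, params.dr_max_spacer + 1))
    while True:
        unit = decode(_BACKGROUND_BASES[rng.integers(0, 4, size=unit_len)])
        if "GGG" not in unit and "CCC" not in unit:
            break
    mid = decode(_BACKGROUND_BASES[rng.integers(0, 4, size=spacer)])
    core = unit + mid + unit
    d = unit_len + spacer
    # guards break the shift-d agreement just outside the planted site
    lg = next(b for b in "ACGT" if b != core[d - 1])
    rg = next(b for b in "ACGT" if b != core[unit_len])
    return core, lg, rg, {}


def _build_zdna(rng: np.random.Generator, params: ScanParams):
    cycles = [
        (a, b)
        for a, b in (("G", "T"), ("A", "C"))
        if a + b in params.z_allowed_dinucleotides
        and b + a in params.z_allowed_dinucleotides
    ]
    if not cycles:
        raise SimulationError(
            "no non-self-complementary alternating dinucleotide available "
            "for Z-DNA planting under these parameters"
        )
    a, b = cycles[int(rng.integers(len(cycles)))]
    hi = min(19, params.z_min_len + 7)  # <= 19 nt: cannot double as a direct repeat
    length = int(rng.integers(params.z_min_len, hi + 1))
    start_first = bool(rng.integers(2))
    chars = [(a if (i % 2 == 0) == start_first else b) for i in range(length)]
    core = "".join(chars)
    return core, core[0], core[-1], {}


def _self_collision(structure: str, block: str, params: ScanParams) -> bool:
    """A drawn instance (guards included) can, by chance, contain a motif
    of *another* class — e.g. an accidental direct repeat inside a
    purine-rich mirror repeat or spanning the near-periodic runs of a G4 —
    which the cross-class exclusion would then remove.  Reject such blocks
    at construction time."""
    from .scan import find_direct_repeats, find_inverted_repeats, \
        find_triplex_mirror_repeats

    if structure in ("g4", "triplex"):
        return bool(find_direct_repeats(block, params))
    if structure == "slipped":
        return bool(
            find_inverted_repeats(block, params)
            or find_triplex_mirror_repeats(block, params)
        )
    return False


def _build_instance(
    structure: str,
    rng: np.random.Generator,
    params: ScanParams,
    g_run_length: int = 0,
):
    builders = {
        "g4": lambda: _build_g4(rng, params, g_run_length or params.g4_min_run),
        "cruciform": lambda: _build_cruciform(rng, params),
        "triplex": lambda: _build_triplex(rng, params),
        "slipped": lambda: _build_slipped(rng, params),
        "zdna": lambda: _build_zdna(rng, params),
    }
    if structure not in builders:
        raise ValueError(f"unknown structure {structure!r}")
    for _ in range(50):
        core, lg, rg, attrs = builders[structure]()
        if not _self_collision(structure, lg + core + rg, params):
            return core, lg, rg, attrs
    raise SimulationError(
        f"could not draw a collision-free {structure} instance"
    )


_CLASS_OF = {
    "g4": StructureClass.G4,
    "cruciform": StructureClass.CRUCIFORM,
    "triplex": StructureClass.TRIPLEX,
    "slipped": StructureClass.SLIPPED,
    "zdna": StructureClass.ZDNA,
}


def plant_motif(
    seq: str,
    structure: str,
    position: int,
    strand: Optional[str] = None,
    params: Optional[ScanParams] = None,
    rng: Optional[np.random.Generator] = None,
    g_run_length: int = 0,
) -> tuple[str, MotifHit]:
    """Plant one motif instance at ``position`` and return the modified
    sequence with the ground-truth hit.

    For G4, ``strand="template"`` inserts the reverse complement of the
    instance so the forward sequence shows C-runs and the scanner reports a
    REVERSE_COMPLEMENT-strand hit.  Raises :class:`SimulationError` when
    the instance does not fit or is not recovered exactly by the scanner
    (e.g. because it collides with neighbouring sequence content).
    """
    params = params or ScanParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    core, lg, rg, _ = _build_instance(structure, rng, params, g_run_length)
    template = structure == "g4" and strand == "template"
    if template:
        core = revcomp(core)
        lg, rg = revcomp(rg), revcomp(lg)
    start, end = position, position + len(core)
    if position - len(lg) < 0 or end + len(rg) > len(seq):
        raise SimulationError("planted instance does not fit at this position")
    new_seq = seq[: start - len(lg)] + lg + core + rg + seq[end + len(rg) :]
    cls = _CLASS_OF[structure]
    want_strand = (
        Strand.REVERSE_COMPLEMENT if template else Strand.FORWARD
    )
    hits = scan_all(new_seq, params)[cls]
    match = [
        h
        for h in hits
        if h.start == start and h.end == end and h.scanned_strand is want_strand
    ]
    if not match:
        raise SimulationError(
            f"planted {structure} at {position} was not recovered exactly "
            "(collision with surrounding sequence)"
        )
    return new_seq, match[0]


# ---------------------------------------------------------------------------
# intron assembly

@dataclass
class _PlannedPlant:
    structure: str
    strand: Optional[str]
    core: str
    lg: str
    rg: str
    g_run_length: int
    start: int = -1

    @property
    def end(self) -> int:
        return self.start + len(self.core)


def _draw_plants(
    rng: np.random.Generator,
    region: str,
    length: int,
    config: SimulationConfig,
) -> list[_PlannedPlant]:
    scale = (
        length / config.intron_length_median
        if config.confound_intron_length
        else 1.0
    )
    plants = []
    for key in sorted(
        config.plant_rates, key=lambda k: (k[0], k[1], k[2] or "")
    ):
        structure, reg, strand = key
        if reg != region:
            continue
        rate = config.plant_rates[key] * scale
        for _ in range(int(rng.poisson(rate))):
            g_run = 0
            if structure == "g4":
                lo, hi = config.g_run_length_range
                g_run = int(rng.integers(lo, hi + 1))
            core, lg, rg, _ = _build_instance(
                structure, rng, config.scan_params, g_run
            )
            if structure == "g4" and strand == "template":
                core, lg, rg = revcomp(core), revcomp(rg), revcomp(lg)
            plants.append(_PlannedPlant(structure, strand, core, lg, rg, g_run))
    return plants


def _place_plants(
    rng: np.random.Generator,
    plants: list[_PlannedPlant],
    length: int,
) -> bool:
    taken: list[tuple[int, int]] = []
    for plant in plants:
        span = len(plant.core) + len(plant.lg) + len(plant.rg)
        lo = _MARGIN + len(plant.lg)
        hi = length - _MARGIN - len(plant.core) - len(plant.rg)
        if hi < lo:
            return False
        placed = False
        for _ in range(100):
            pos = int(rng.integers(lo, hi + 1))
            if all(
                pos - _MIN_GAP >= e or pos + span + _MIN_GAP <= s
                for s, e in taken
            ):
                plant.start = pos
                taken.append((pos - len(plant.lg), pos + len(plant.core) + len(plant.rg)))
                placed = True
                break
        if not placed:
            return False
    return True


def _required_space(plants: list[_PlannedPlant]) -> int:
    return sum(len(p.core) + len(p.lg) + len(p.rg) + _MIN_GAP for p in plants)


def _make_intron(
    rng: np.random.Generator,
    length: int,
    region: str,
    config: SimulationConfig,
) -> tuple[str, list[PlantedMotif], dict, int]:
    """Build one intron; returns (sequence, planted truth records, scan
    hits, accidental-hit count)."""
    params = config.scan_params
    n_plants = None
    for _attempt in range(config.max_intron_attempts):
        # fresh instances every attempt so one unlucky draw cannot wedge
        # the whole intron; counts are re-drawn too, which conditions the
        # realized plant set on being placeable and exactly recoverable
        plants = _draw_plants(rng, region, length, config)
        n_plants = len(plants)
        if _required_space(plants) > length - 2 * _MARGIN:
            continue
        if not _place_plants(rng, plants, length):
            continue
        codes = _background_codes(length, config.gc_content, rng)
        for p in plants:
            block = encode(p.lg + p.core + p.rg)
            codes[p.start - len(p.lg) : p.end + len(p.rg)] = block
        seq = decode(codes)
        hits = scan_all(seq, params)
        ok = True
        for p in plants:
            cls = _CLASS_OF[p.structure]
            want = (
                Strand.REVERSE_COMPLEMENT
                if p.structure == "g4" and p.strand == "template"
                else Strand.FORWARD
            )
            if not any(
                h.start == p.start and h.end == p.end and h.scanned_strand is want
                for h in hits[cls]
            ):
                ok = False
                break
        if not ok:
            continue
        planted = [
            PlantedMotif(p.structure, region, p.strand, p.start, p.end, p.g_run_length)
            for p in plants
        ]
        n_hits = sum(len(v) for v in hits.values())
        return seq, planted, hits, n_hits - len(plants)
    raise SimulationError(
        f"could not realize {n_plants} planted instances in an intron of "
        f"length {length} after {config.max_intron_attempts} attempts "
        "(plant rates may be infeasible for this intron length)"
    )


# ---------------------------------------------------------------------------
# dataset assembly

def _entry_design(
    up_profile, down_profile
) -> dict[str, float]:
    design = {
        "upstream_length": float(up_profile.intron_length),
        "downstream_length": float(down_profile.intron_length),
    }
    for region, prof in (("upstream", up_profile), ("downstream", down_profile)):
        c = prof.counts
        design[f"{region}_cruciform"] = float(c["cruciform"])
        design[f"{region}_g4"] = float(c["g4_template"] + c["g4_nontemplate"])
        design[f"{region}_slipped"] = float(c["slipped"])
        design[f"{region}_triplex"] = float(c["triplex"])
        design[f"{region}_zdna"] = float(c["zdna"])
    return design


def _draw_intron_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    raw = rng.lognormal(
        math.log(config.intron_length_median), config.intron_length_sigma
    )
    return int(min(max(raw, config.intron_length_min), config.intron_length_max))


def simulate_truth(config: SimulationConfig) -> TruthTable:
    """Draw lengths, planted counts and labels without building sequences.

    The design vector holds the planted counts directly (no background
    occurrences exist without sequences); useful for fast statistical
    experiments where scanning is not under test.
    """
    rng = np.random.default_rng(config.seed)
    beta = config.true_beta
    lo, hi = config.g_run_length_range
    entries = []
    for i in range(config.n_entries):
        lengths = {
            "upstream": _draw_intron_length(rng, config),
            "downstream": _draw_intron_length(rng, config),
        }
        design = {
            "upstream_length": float(lengths["upstream"]),
            "downstream_length": float(lengths["downstream"]),
        }
        for region in ("upstream", "downstream"):
            for s in ("cruciform", "g4", "slipped", "triplex", "zdna"):
                design[f"{region}_{s}"] = 0.0
        planted = []
        max_up_template_run = 0
        for key in sorted(
            config.plant_rates, key=lambda k: (k[0], k[1], k[2] or "")
        ):
            structure, region, strand = key
            scale = (
                lengths[region] / config.intron_length_median
                if config.confound_intron_length
                else 1.0
            )
            count = int(rng.poisson(config.plant_rates[key] * scale))
            for _ in range(count):
                g_run = int(rng.integers(lo, hi + 1)) if structure == "g4" else 0
                planted.append(
                    PlantedMotif(structure, region, strand, -1, -1, g_run)
                )
                design[f"{region}_{structure}"] += 1.0
                if structure == "g4" and strand == "template" and region == "upstream":
                    max_up_template_run = max(max_up_template_run, g_run)
        lp = float(beta["intercept"]) + sum(
            float(beta[c]) * design[c] for c in DESIGN_COLUMNS
        )
        lp += config.g_run_effect * max_up_template_run
        prob = float(expit(lp))
        label = "SKIPPED" if rng.random() < prob else "CONSTITUTIVE"
        entries.append(
            TruthEntry(
                entry_id=f"e{i:06d}",
                orientation="+",
                upstream_length=lengths["upstream"],
                downstream_length=lengths["downstream"],
                planted=planted,
                design=design,
                n_accidental=0,
                linear_predictor=lp,
                probability=prob,
                label=label,
            )
        )
    return TruthTable(entries, config)


def _write_fasta(handle, name: str, seq: str, width: int = 60) -> None:
    handle.write(f">{name}\n")
    for i in range(0, len(seq), width):
        handle.write(seq[i : i + width] + "\n")


def simulate_dataset(
    config: SimulationConfig, out_dir: Optional[str] = None
) -> TruthTable:
    """Generate a full synthetic dataset: per-entry contigs (FASTA), 3-exon
    gene models (GFF3), SKIPPED/CONSTITUTIVE labels (TSV) and the ground
    truth (TSV).  Returns the in-memory :class:`TruthTable`; files are
    written only when ``out_dir`` is given (byte-identical across runs with
    the same config and seed)."""
    rng = np.random.default_rng(config.seed)
    beta = config.true_beta
    params = config.scan_params
    entries: list[TruthEntry] = []
    fasta = gff = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        fasta = open(os.path.join(out_dir, "genome.fa"), "w")
        gff = open(os.path.join(out_dir, "annotation.gff3"), "w")
        gff.write("##gff-version 3\n")
        labels_fh = open(os.path.join(out_dir, "labels.tsv"), "w")
        labels_fh.write("entry_id\tlabel\n")
    try:
        for i in range(config.n_entries):
            entry_id = f"e{i:06d}"
            orientation = "+" if rng.random() < 0.5 else "-"
            exon_lens = [
                int(rng.integers(*config.exon_length_range)) for _ in range(3)
            ]
            up_len = _draw_intron_length(rng, config)
            down_len = _draw_intron_length(rng, config)
            up_seq, up_planted, up_hits, up_acc = _make_intron(
                rng, up_len, "upstream", config
            )
            down_seq, down_planted, down_hits, down_acc = _make_intron(
                rng, down_len, "downstream", config
            )
            up_prof = profile_intron(
                up_seq, Region.UPSTREAM, params, exon_ref=entry_id, _hits=up_hits
            )
            down_prof = profile_intron(
                down_seq, Region.DOWNSTREAM, params, exon_ref=entry_id, _hits=down_hits
            )
            design = _entry_design(up_prof, down_prof)
            lp = float(beta["intercept"]) + sum(
                float(beta[c]) * design[c] for c in DESIGN_COLUMNS
            )
            lp += config.g_run_effect * up_prof.max_g_run_template
            prob = float(expit(lp))
            label = "SKIPPED" if rng.random() < prob else "CONSTITUTIVE"
            entries.append(
                TruthEntry(
                    entry_id=entry_id,
                    orientation=orientation,
                    upstream_length=up_len,
                    downstream_length=down_len,
                    planted=up_planted + down_planted,
                    design=design,
                    n_accidental=up_acc + down_acc,
                    linear_predictor=lp,
                    probability=prob,
                    label=label,
                )
            )
            if out_dir is not None:
                exon_bg = [
                    decode(_background_codes(L, config.gc_content, rng))
                    for L in exon_lens
                ]
                pad5 = decode(_background_codes(config.pad, config.gc_content, rng))
                pad3 = decode(_background_codes(config.pad, config.gc_content, rng))
                layout = (
                    pad5 + exon_bg[0] + up_seq + exon_bg[1] + down_seq
                    + exon_bg[2] + pad3
                )
                n = len(layout)
                # sense-layout exon intervals
                e1 = (config.pad, config.pad + exon_lens[0])
                e2 = (e1[1] + up_len, e1[1] + up_len + exon_lens[1])
                e3 = (e2[1] + down_len, e2[1] + down_len + exon_lens[2])
                if orientation == "+":
                    contig = layout
                    exons = [e1, e2, e3]
                else:
                    contig = revcomp(layout)
                    exons = sorted((n - e[1], n - e[0]) for e in (e1, e2, e3))
                _write_fasta(fasta, entry_id, contig)
                gene_start = exons[0][0] + 1
                gene_end = exons[-1][1]
                gff.write(
                    f"{entry_id}\tnonbsplice\tgene\t{gene_start}\t{gene_end}\t.\t"
                    f"{orientation}\t.\tID=gene:{entry_id}\n"
                )
                gff.write(
                    f"{entry_id}\tnonbsplice\tmRNA\t{gene_start}\t{gene_end}\t.\t"
                    f"{orientation}\t.\tID={entry_id};Parent=gene:{entry_id}\n"
                )
                for j, (s, t) in enumerate(exons):
                    gff.write(
                        f"{entry_id}\tnonbsplice\texon\t{s + 1}\t{t}\t.\t"
                        f"{orientation}\t.\tID={entry_id}.exon{j + 1};"
                        f"Parent={entry_id}\n"
                    )
                labels_fh.write(f"{entry_id}\t{label}\n")
    finally:
        if out_dir is not None:
            fasta.close()
            gff.close()
            labels_fh.close()
    truth = TruthTable(entries, config)
    if out_dir is not None:
        truth.to_frame().to_csv(
            os.path.join(out_dir, "truth.tsv"), sep="\t", index=False
        )
        truth.planted_frame().to_csv(
            os.path.join(out_dir, "planted.tsv"), sep="\t", index=False
        )
    return truth
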