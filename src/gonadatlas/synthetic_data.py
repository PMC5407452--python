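"""Seed-reproducible synthetic expression atlases with known ground truth.

The generator emulates the design of a developmental expression atlas of
human adrenal gland, testis and ovary spanning roughly 42-74 days post
conception (dpc): 53 samples (17 adrenal, 20 testis, 10 ovary, 6 one-organ
controls), staged on the Carnegie/Fetal scale and mapped to midpoint ages
in dpc, processed in two batches.

Planted gene profiles cover the qualitative shapes seen in such atlases:

* ``flat`` — constant baseline everywhere (background genes);
* ``tissue_offset`` — constant baseline plus an offset in target tissues
  (tissue-specific but time-invariant genes);
* ``sigmoid`` — a BALT sigmoid transition in target tissues (e.g. the
  coordinated onset of testicular steroidogenesis around 55-56 dpc);
* ``pulse`` — a transient Gaussian bump (the SRY-like early-testis wave,
  high around 45 dpc and fading by ~57 dpc).

Expression is simulated on the log2 scale as profile value + additive
per-batch offset + Gaussian noise; every planted parameter is recorded in
a truth table so downstream stages can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .balt import BALTParams, balt_evaluate

__all__ = [
    "DEFAULT_STAGE_MAP",
    "STAGE_ORDER",
    "TISSUES",
    "CONTROL_SUBTYPES",
    "DesignConfig",
    "TruthProfile",
    "PanelConfig",
    "SimResult",
    "study_mirror_design",
    "build_design",
    "default_panel",
    "eval_truth_profile",
    "simulate_atlas",
    "make_annotation",
]

#: Stage labels in developmental order.
STAGE_ORDER = ("CS17", "CS18", "CS19", "CS20", "CS21", "CS22", "CS23",
               "F1", "F2", "F3")

#: Midpoint age (dpc) of each Carnegie/Fetal stage. These midpoints span the
#: 42-74 dpc window of the atlas design; they are configurable wherever a
#: stage map is consumed.
DEFAULT_STAGE_MAP: dict[str, float] = {
    "CS17": 42.0, "CS18": 45.0, "CS19": 48.0, "CS20": 50.0, "CS21": 52.0,
    "CS22": 54.0, "CS23": 56.5, "F1": 60.0, "F2": 66.0, "F3": 73.0,
}

TISSUES = ("adrenal", "testis", "ovary", "control")
CONTROL_SUBTYPES = ("spine", "brain", "muscle", "heart", "kidney", "liver")

_SAMPLE_COLUMNS = ["sample_id", "tissue", "control_subtype", "karyotype",
                   "stage", "age_dpc", "batch"]


def validate_stage_map(stage_map: Mapping[str, float],
                       order: Sequence[str] = STAGE_ORDER) -> None:
    """Check midpoints are strictly increasing along the stage order and
    inside [35, 80] dpc."""
    prev = -math.inf
    for stage in order:
        if stage not in stage_map:
            continue
        v = float(stage_map[stage])
        if not 35.0 <= v <= 80.0:
            raise ValueError(f"stage midpoint {stage}={v} outside [35, 80] dpc")
        if v <= prev:
            raise ValueError(f"stage midpoints not increasing at {stage}")
        prev = v


@dataclass(frozen=True)
class DesignConfig:
    """Per-tissue sample counts and stage allocations for a design.

    ``stages`` maps a tissue to the exact list of stage labels to use (its
    length must equal the tissue's count). ``n_batches`` batches are
    assigned round-robin within each tissue so batch and tissue are not
    confounded.
    """

    counts: Mapping[str, int]
    stages: Mapping[str, Sequence[str]]
    n_batches: int = 2
    stage_map: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MAP))


def study_mirror_design() -> DesignConfig:
    """The atlas study design: 53 samples across four tissue groups.

    Testis allocation places 9 samples in CS18-CS22 ("early",
    pre-steroidogenic), 3 at the CS23 boundary and 8 in F1-F3 ("late",
    post-steroidogenic). Controls are one organ each of spine, brain,
    muscle, heart, kidney and liver, all 46,XY.
    """
    stages = {
        "adrenal": ["CS18", "CS18", "CS19", "CS19", "CS20", "CS20", "CS21",
                    "CS21", "CS22", "CS22", "CS23", "CS23", "F1", "F1",
                    "F2", "F2", "F3"],
        "testis": ["CS18", "CS18", "CS19", "CS19", "CS20", "CS20", "CS21",
                   "CS22", "CS22",                       # early, n=9
                   "CS23", "CS23", "CS23",               # boundary, n=3
                   "F1", "F1", "F1", "F2", "F2", "F2", "F3", "F3"],  # late, n=8
        "ovary": ["CS19", "CS20", "CS21", "CS22", "CS23", "F1", "F1",
                  "F2", "F2", "F3"],
        "control": ["CS18", "CS20", "CS22", "CS23", "F1", "F3"],
    }
    return DesignConfig(
        counts={"adrenal": 17, "testis": 20, "ovary": 10, "control": 6},
        stages=stages,
    )


def build_design(config: DesignConfig | str = "study-mirror",
                 seed: int = 0) -> pd.DataFrame:
    """Build a sample metadata table from a design configuration.

    Ovary samples are 46,XX; adrenal, testis and control samples are 46,XY
    (the study design deliberately used 46,XY controls so Y-chromosome
    effects are testable). Deterministic for a fixed seed.
    """
    if isinstance(config, str):
        if config != "study-mirror":
            raise ValueError(f"unknown design preset {config!r}")
        config = study_mirror_design()
    validate_stage_map(config.stage_map)

    records = []
    for tissue, count in config.counts.items():
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue label {tissue!r}")
        if count < 0:
            raise ValueError(f"negative sample count for {tissue!r}")
        stages = list(config.stages.get(tissue, []))
        if count and len(stages) != count:
            raise ValueError(
                f"{tissue}: {len(stages)} stages allocated for {count} samples")
        for i in range(count):
            stage = stages[i]
            if stage not in config.stage_map:
                raise ValueError(f"stage {stage!r} missing from stage map")
            records.append({
                "sample_id": f"{tissue[:3].upper()}_{i + 1:02d}",
                "tissue": tissue,
                "control_subtype": CONTROL_SUBTYPES[i % len(CONTROL_SUBTYPES)]
                if tissue == "control" else "",
                "karyotype": "46,XX" if tissue == "ovary" else "46,XY",
                "stage": stage,
                "age_dpc": float(config.stage_map[stage]),
                "batch": f"b{1 + i % max(config.n_batches, 1)}",
            })
    design = pd.DataFrame(records, columns=_SAMPLE_COLUMNS)
    design.attrs["seed"] = seed
    return design


@dataclass(frozen=True)
class TruthProfile:
    """Ground-truth expression profile of one planted gene.

    ``params`` depend on the class: flat {b}; tissue_offset {b, d};
    sigmoid {B, A, L, T, optionally l_by_tissue overriding L per tissue};
    pulse {b, h, mu, w}. Outside the target tissues, sigmoid genes sit at
    their basis B and offset/pulse genes at their baseline b.

    The per-tissue localisation override exists because a transition can
    complete before the observation window in one tissue (adrenal
    steroidogenesis precedes the atlas window) while being captured mid-rise
    in another (testis).
    """

    gene_id: str
    profile_class: str
    target_tissues: frozenset[str] = frozenset()
    params: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.25

    def __post_init__(self):
        if self.profile_class not in ("flat", "tissue_offset", "sigmoid", "pulse"):
            raise ValueError(f"unknown profile class {self.profile_class!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.profile_class == "pulse" and not self.params.get("w", 1.0) > 0:
            raise ValueError("pulse width w must be positive")
        if self.profile_class == "sigmoid" and not self.params.get("T", 1.0) > 0:
            raise ValueError("sigmoid T must be positive")
        object.__setattr__(self, "target_tissues", frozenset(self.target_tissues))


def eval_truth_profile(profile: TruthProfile, tissue: str, t: float) -> float:
    """Noise-free log2 expression of a planted gene at (tissue, time)."""
    if not 35.0 <= t <= 80.0:
        raise ValueError(f"time {t} dpc outside the supported [35, 80] window")
    p = profile.params
    cls = profile.profile_class
    in_target = tissue in profile.target_tissues
    if cls == "flat":
        return float(p["b"])
    if cls == "tissue_offset":
        return float(p["b"]) + (float(p["d"]) if in_target else 0.0)
    if cls == "sigmoid":
        if not in_target:
            return float(p["B"])
        loc = p.get("l_by_tissue", {}).get(tissue, p["L"])
        return balt_evaluate(
            BALTParams(B=float(p["B"]), A=float(p["A"]), L=float(loc),
                       T=float(p["T"])), t)
    if cls == "pulse":
        if not in_target:
            return float(p["b"])
        z = (t - float(p["mu"])) / float(p["w"])
        return float(p["b"]) + float(p["h"]) * math.exp(-0.5 * z * z)
    raise ValueError(f"unknown profile class {cls!r}")  # pragma: no cover


@dataclass(frozen=True)
class PanelConfig:
    """Counts and magnitudes for the default truth panel."""

    n_flat: int = 143
    noise_sd: float = 0.25
    batch_sd: float = 0.3


# Planted signal genes, named after the genes whose published dynamics they
# emulate. Steroidogenic genes transition at L=55.5 dpc in testis but are
# already high throughout the window in adrenal (override L=42).
def _signal_profiles(noise_sd: float) -> list[TruthProfile]:
    steroid = ["CYP17A1", "CYP11A1", "STAR", "HSD3B2", "LHCGR", "HSD17B3"]
    curvi = ["SOX9", "CITED1", "DHH"]
    secreted = ["AMH", "INHA", "INSL3"]
    profiles = [
        TruthProfile("SRY", "pulse", frozenset({"testis"}),
                     {"b": 5.0, "h": 1.5, "mu": 45.0, "w": 6.0}, noise_sd),
    ]
    for g in steroid:
        profiles.append(TruthProfile(
            g, "sigmoid", frozenset({"adrenal", "testis"}),
            {"B": 6.0, "A": 3.0, "L": 55.5, "T": 4.0,
             "l_by_tissue": {"adrenal": 42.0}}, noise_sd))
    for g in curvi:
        profiles.append(TruthProfile(
            g, "sigmoid", frozenset({"testis"}),
            {"B": 6.0, "A": 1.0, "L": 70.0, "T": 25.0}, noise_sd))
    for g in secreted:
        profiles.append(TruthProfile(
            g, "sigmoid", frozenset({"testis"}),
            {"B": 6.0, "A": 2.0, "L": 57.0, "T": 6.0}, noise_sd))
    # Tissue-identity marker blocks: constant tissue-specific elevation, the
    # kind of signature that makes whole atlases cluster by organ.
    markers = {
        frozenset({"adrenal"}): [("MC2R", 3.0), ("MRAP", 2.5), ("ASB4", 3.0),
                                 ("NPR3", 2.5), ("GRB14", 2.2), ("NRK", 2.8),
                                 ("TDGF1", 2.0), ("GNRHR", 2.4),
                                 ("SULT2A1", 3.2), ("CYP11B1", 3.0)],
        # Sertoli-lineage signature, established well before the atlas window
        frozenset({"testis"}): [("DMRT1", 2.5), ("CLDN11", 2.0),
                                ("PTGDS", 2.2), ("TEX14", 1.8),
                                ("SEMA3C", 1.6), ("ARX", 1.5),
                                ("FGF9", 3.0), ("CYP26B1", 2.4),
                                ("SHBG", 2.2), ("PDGFA", 2.0),
                                ("VNN1", 2.0), ("GADD45G", 1.8)],
        frozenset({"ovary"}): [("RSPO1", 2.5), ("WNT4", 2.2), ("FOXL2", 2.8),
                               ("LIN28A", 2.4), ("IRX3", 2.0), ("MSX1", 1.8),
                               ("LGR5", 2.2), ("FST", 2.6), ("KITLG", 2.0),
                               ("ZGLP1", 2.4),
                               # germ-cell expansion signature of the early
                               # fetal ovary
                               ("DAZL", 3.0), ("DDX4", 2.8), ("MAEL", 2.5),
                               ("PIWIL2", 2.4), ("SYCP3", 2.6), ("STRA8", 2.2)],
        frozenset({"testis", "ovary"}): [("WT1", 2.6), ("GATA4", 2.4),
                                         ("LHX9", 2.2), ("EMX2", 2.0),
                                         ("POU5F1", 2.6), ("NANOG", 2.4)],
    }
    for targets, genes in markers.items():
        for gene, d in genes:
            profiles.append(TruthProfile(gene, "tissue_offset", targets,
                                         {"b": 5.5, "d": d}, noise_sd))
    return profiles


def default_panel(config: PanelConfig | None = None) -> list[TruthProfile]:
    """The default truth panel: 1 SRY-like chrY pulse, 6 shared
    adrenal+testis steroidogenic sigmoids, 3 SOX9-like curvilinear genes,
    3 secreted late-testis genes, 44 tissue-identity marker genes
    (adrenal / testis / ovary / shared-gonad offset blocks), and flat
    background genes (baselines cycling over 4-10 log2 units)."""
    config = config or PanelConfig()
    profiles = _signal_profiles(config.noise_sd)
    for i in range(config.n_flat):
        profiles.append(TruthProfile(
            f"GENE{i + 1:04d}", "flat", frozenset(),
            {"b": 4.0 + 0.5 * (i % 13)}, config.noise_sd))
    return profiles


@dataclass
class SimResult:
    """A simulated atlas: expression matrix, truth table, design, seed."""

    matrix: pd.DataFrame
    truth: pd.DataFrame
    design: pd.DataFrame
    seed: int


def _truth_table(panel: Sequence[TruthProfile]) -> pd.DataFrame:
    rows = []
    for p in panel:
        row = {"gene": p.gene_id, "profile_class": p.profile_class,
               "target_tissues": ",".join(sorted(p.target_tissues)),
               "noise_sd": p.noise_sd}
        for key, val in p.params.items():
            if key == "l_by_tissue":
                row["l_by_tissue"] = ";".join(
                    f"{k}={v}" for k, v in sorted(val.items()))
            else:
                row[key] = val
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def simulate_atlas(design: pd.DataFrame,
                   panel: Sequence[TruthProfile] | PanelConfig | None = None,
                   seed: int = 0,
                   batch_sd: float | None = None) -> SimResult:
    """Simulate a log2 expression matrix over a design from a truth panel.

    Matrix entry = noise-free profile value + per-(batch, gene) additive
    offset drawn Normal(0, batch_sd) + Gaussian(0, noise_sd) measurement
    noise. Identical seeds reproduce the matrix bit-for-bit.
    """
    if len(design) == 0:
        raise ValueError("design is empty")
    if panel is None or isinstance(panel, PanelConfig):
        cfg = panel or PanelConfig()
        if batch_sd is None:
            batch_sd = cfg.batch_sd
        panel = default_panel(cfg)
    else:
        panel = list(panel)
    if len(panel) == 0:
        raise ValueError("truth panel contains no genes")
    if batch_sd is None:
        batch_sd = 0.3

    rng = np.random.default_rng(seed)
    genes = [p.gene_id for p in panel]
    samples = design["sample_id"].tolist()

    conditions = list(zip(design["tissue"], design["age_dpc"].astype(float)))
    clean = np.empty((len(genes), len(samples)))
    for gi, prof in enumerate(panel):
        for si, (tissue, age) in enumerate(conditions):
            clean[gi, si] = eval_truth_profile(prof, tissue, age)

    batches = sorted(design["batch"].unique())
    offsets = {b: rng.normal(0.0, batch_sd, size=len(genes)) if batch_sd > 0
               else np.zeros(len(genes)) for b in batches}
    batch_mat = np.column_stack([offsets[b] for b in design["batch"]])

    noise_sd = np.array([p.noise_sd for p in panel])[:, None]
    noise = rng.standard_normal(clean.shape) * noise_sd

    matrix = pd.DataFrame(clean + batch_mat + noise, index=pd.Index(genes, name="gene"),
                          columns=samples)
    truth = _truth_table(panel)
    truth["noise_sd"] = [p.noise_sd for p in panel]
    return SimResult(matrix=matrix, truth=truth, design=design.copy(), seed=seed)


def make_annotation(panel: Sequence[TruthProfile] | None = None) -> pd.DataFrame:
    """Gene annotation for a truth panel: chromosome, secreted flag, category.

    SRY is placed on chromosome Y; the secreted flag marks the classic
    testis biomarkers AMH, INHA and INSL3; steroidogenic sigmoids carry the
    'steroidogenesis' category and everything unlabelled is left blank
    (treated as novel by the categoriser).
    """
    panel = panel if panel is not None else default_panel()
    secreted = {"AMH", "INHA", "INSL3"}
    steroid = {"CYP17A1", "CYP11A1", "STAR", "HSD3B2", "LHCGR", "HSD17B3"}
    rows = []
    for i, p in enumerate(panel):
        g = p.gene_id.upper()
        rows.append({
            "gene": g,
            "chromosome": "Y" if g == "SRY" else str(1 + i % 22),
            "secreted": g in secreted,
            "category": "steroidogenesis" if g in steroid else "",
            "biotype": "protein_coding",
        })
    return pd.DataFrame(rows).set_index("gene")
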