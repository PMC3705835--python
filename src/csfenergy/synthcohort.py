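"""Quantile-anchored synthetic CSF cohorts.

The generator reproduces the statistical structure of a published reference
cohort of 8183 lumbar punctures split into eight cytological syndromes
(controls n=235, GO 64, GP 766, LO 1200, LP 1610, MO 2699, MP 1457, and
tumorous TO 31 + TP 121).  For each group only seven CEB quantile anchors
are published — minimum, 2.5th percentile, quartiles, median, 97.5th
percentile, maximum — so CEB is drawn by inverting a piecewise-linear
quantile function through those anchors:

* between the 2.5th and 97.5th percentile anchors, linearly in CEB;
* below the 2.5th percentile, linearly in the transformed coordinate
  log10(40 - CEB), so the heavy negative tails (GP minimum -2996.50) are
  reachable with total probability 0.025 without a point mass at the
  printed minimum;
* above the 97.5th percentile, linearly in CEB up to the printed maximum.

Every other analyte of a record is then back-solved or drawn so that the
record is internally consistent with its generating syndrome: CSF lactate
is set to glucose x (38 - CEB)/18, the exact inversion of the score, and
cell counts, differential fractions, chemistry and immunology are drawn
from group-conditional ranges that satisfy the syndrome definitions
(controls pass every reference-range check; pleocytosis groups exceed
4 leukocytes/µL with the right predominant class; tumorous records carry
malignant cells).  In the GP group, a configurable fraction (default 33.8 %)
of the CEB > 10 subgroup receives an artificial blood admixture
(erythrocytes > 100/µL), mirroring the reference cohort's substructure.

Randomness uses a single root seed with named substreams per group and per
variable, so adding a variable never perturbs existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .classify import Syndrome
from .metrics import ATP_AEROBIC, ATP_ANAEROBIC_PENALTY, TRANSFORM_OFFSET
from .records import COLUMNS

#: Cumulative probabilities of the seven anchors.
ANCHOR_PROBS = (0.0, 0.025, 0.25, 0.5, 0.75, 0.975, 1.0)

SPEC_VERSION = 1

#: Fixed generation order (also the concatenation order before shuffling).
GROUP_ORDER = (
    Syndrome.CONTROL, Syndrome.GO, Syndrome.GP, Syndrome.LO, Syndrome.LP,
    Syndrome.MO, Syndrome.MP, Syndrome.TO, Syndrome.TP,
)


@dataclass(frozen=True)
class GroupQuantileSpec:
    """Calibration of one syndrome group: size and seven CEB anchors."""

    group: Syndrome
    n: int
    anchors: tuple[float, ...]  # (min, p2.5, Q1, median, Q3, p97.5, max)

    def __post_init__(self) -> None:
        if len(self.anchors) != len(ANCHOR_PROBS):
            raise ValueError(f"expected {len(ANCHOR_PROBS)} anchors, got {len(self.anchors)}")
        if any(b < a for a, b in zip(self.anchors, self.anchors[1:])):
            raise ValueError(f"anchors must be nondecreasing: {self.anchors}")
        if self.anchors[-1] > ATP_AEROBIC:
            raise ValueError(f"anchor exceeds the CEB maximum {ATP_AEROBIC}: {self.anchors}")
        if self.n < 1:
            raise ValueError(f"group size must be >= 1, got {self.n}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus full provenance for reproduction."""

    frame: pd.DataFrame            # record schema + group_true + ceb columns
    seed: int
    spec_version: int
    scale: float

    def __len__(self) -> int:
        return len(self.frame)


def _substream(seed: int, *names: str) -> np.random.Generator:
    """Independent generator for a named (group, variable) substream."""
    keys = [zlib.crc32(name.encode()) for name in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def load_default_specs() -> tuple[dict[Syndrome, GroupQuantileSpec], dict]:
    """Packaged group anchors and generator plumbing configuration."""
    text = resources.files("csfenergy.data").joinpath("group_anchors.yaml").read_text()
    raw = yaml.safe_load(text)
    specs = {
        Syndrome(name): GroupQuantileSpec(Syndrome(name), int(g["n"]), tuple(g["anchors"]))
        for name, g in raw["groups"].items()
    }
    return specs, raw["plumbing"]


def sample_ceb(spec: GroupQuantileSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` CEB values by inverse-CDF through the group's anchors."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else _substream(int(seed), spec.group.value, "ceb")
    u = rng.uniform(size=n)
    v = np.asarray(spec.anchors, dtype=float)
    out = np.empty(n)

    lo, hi = u < ANCHOR_PROBS[1], u > ANCHOR_PROBS[5]
    mid = ~(lo | hi)
    out[mid] = np.interp(u[mid], ANCHOR_PROBS[1:6], v[1:6])
    # lower tail: linear in log10(40 - CEB) between the minimum and p2.5
    t_min = np.log10(TRANSFORM_OFFSET - v[0])
    t_p = np.log10(TRANSFORM_OFFSET - v[1])
    t = t_min + (t_p - t_min) * (u[lo] / ANCHOR_PROBS[1])
    out[lo] = TRANSFORM_OFFSET - 10.0**t
    # upper tail: linear in CEB between p97.5 and the maximum
    out[hi] = v[5] + (v[6] - v[5]) * (u[hi] - ANCHOR_PROBS[5]) / (1.0 - ANCHOR_PROBS[5])
    return np.clip(out, v[0], v[6])


def _uniform(rng: np.random.Generator, bounds, size: int) -> np.ndarray:
    lo, hi = bounds
    return rng.uniform(lo, hi, size=size)


def _log_uniform(rng: np.random.Generator, bounds, size: int) -> np.ndarray:
    lo, hi = bounds
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=size)


def realize_group(
    group: Syndrome,
    ceb: np.ndarray,
    seed: int,
    plumbing: dict,
    reference_table=None,
) -> pd.DataFrame:
    """Back-solve full records for one group from its CEB draws.

    Every record satisfies the exact score inversion
    ``lactate = glucose x (38 - CEB) / 18`` and its group's definitional
    constraints, so reclassifying a generated record recovers the
    generating label.
    """
    from .reference import load_reference_table

    if reference_table is None:
        reference_table = load_reference_table()
    n = len(ceb)
    g = group.value

    def rng(var: str) -> np.random.Generator:
        return _substream(seed, g, var)

    ratio = (ATP_AEROBIC - ceb) / ATP_ANAEROBIC_PENALTY  # lactate/glucose
    burst = ceb <= 10.0

    age = _uniform(rng("age"), (19.0, 70.0), n)

    if group == Syndrome.CONTROL:
        # glucose window intersecting the lactate reference range 0.7-2.1
        lac_lo, lac_hi = reference_table.lookup_range("lactate_csf")
        g_lo = np.maximum(plumbing["glucose_control"][0], lac_lo / ratio)
        g_hi = np.minimum(plumbing["glucose_control"][1], lac_hi / ratio)
        g_hi = np.maximum(g_hi, g_lo)
        glucose = g_lo + rng("glucose").uniform(size=n) * (g_hi - g_lo)
        q_glu = _uniform(rng("q_glu"), plumbing["q_glu_control"], n)
    else:
        glucose = np.where(
            burst,
            _uniform(rng("glucose_burst"), plumbing["glucose_burst"], n),
            _uniform(rng("glucose"), plumbing["glucose_default"], n),
        )
        q_glu = np.where(
            burst,
            _uniform(rng("q_glu_burst"), plumbing["q_glu_burst"], n),
            _uniform(rng("q_glu"), plumbing["q_glu_inflamed"], n),
        )
    lactate = glucose * ratio
    glucose_serum = glucose / q_glu

    pleocytic = group in (Syndrome.GP, Syndrome.MP, Syndrome.LP, Syndrome.TP)
    if pleocytic:
        leukocytes = np.floor(_log_uniform(rng("leukocytes"), (5.0, 2000.0), n))
        leukocytes = np.maximum(leukocytes, 5.0)
    else:
        leukocytes = rng("leukocytes").integers(0, 5, size=n).astype(float)

    u = rng("fractions").uniform(size=n)
    if group == Syndrome.CONTROL:
        lymph = 0.6 + 0.2 * u                      # 7:3 balance +/- tolerance
        mono = 1.0 - lymph
        gran = np.zeros(n)
    elif group in (Syndrome.GO, Syndrome.GP):
        gran = 0.5 + 0.4 * u
        lymph = 0.6 * (1.0 - gran)
        mono = 0.4 * (1.0 - gran)
    elif group in (Syndrome.MO, Syndrome.MP):
        mono = 0.55 + 0.3 * u
        lymph = 0.95 * (1.0 - mono)
        gran = 0.05 * (1.0 - mono)
    elif group == Syndrome.LO:
        lymph = 0.92 + 0.07 * u                    # beyond the 0.9 tolerance
        mono = 1.0 - lymph
        gran = np.zeros(n)
    elif group == Syndrome.LP:
        lymph = 0.6 + 0.3 * u
        mono = 0.8 * (1.0 - lymph)
        gran = 0.2 * (1.0 - lymph)
    else:  # TO / TP: malignant flag decides the label, composition is mixed
        lymph = 0.4 + 0.3 * u
        mono = 0.75 * (1.0 - lymph)
        gran = 0.25 * (1.0 - lymph)

    erythrocytes = rng("erythrocytes").integers(0, 51, size=n).astype(float)
    if group == Syndrome.GP:
        admix = (~burst) & (rng("admixture").uniform(size=n) < plumbing["gp_admixture_fraction"])
        erythrocytes[admix] = np.floor(
            _log_uniform(rng("admixture_count"), plumbing["admixture_erythrocytes_range"],
                         n)[admix]
        )

    if group == Syndrome.CONTROL:
        tp_lo, tp_hi = np.array([reference_table.lookup_range("tp_csf", a) for a in age]).T
        tp_csf = tp_lo + rng("tp_csf").uniform(size=n) * (tp_hi - tp_lo)
        qa_lo, qa_hi = np.array([reference_table.lookup_range("q_alb", a) for a in age]).T
        q_alb = qa_lo + rng("q_alb").uniform(size=n) * (qa_hi - qa_lo)
        beta2m = _uniform(rng("beta2m"), (0.5, 1.8), n)
        it = np.zeros((3, n))
    else:
        tp_csf = _uniform(rng("tp_csf"), (250.0, 1500.0), n)
        q_alb = _uniform(rng("q_alb"), (2e-3, 15e-3), n)
        beta2m = _uniform(rng("beta2m"), (0.8, 6.0), n)
        it = np.where(
            rng("it_synthesis").uniform(size=(3, n)) < 0.3,
            rng("it_amount").uniform(5.0, 60.0, size=(3, n)),
            0.0,
        )
    albumin_serum = _uniform(rng("albumin_serum"), (38000.0, 48000.0), n)
    albumin_csf = q_alb * albumin_serum

    frame = pd.DataFrame({
        "record_id": [f"{g}-{i:05d}" for i in range(n)],
        "age_years": age,
        "lactate_csf": lactate,
        "glucose_csf": glucose,
        "glucose_serum": glucose_serum,
        "tp_csf": tp_csf,
        "albumin_csf": albumin_csf,
        "albumin_serum": albumin_serum,
        "beta2m_csf": beta2m,
        "leukocytes": leukocytes,
        "erythrocytes": erythrocytes,
        "fraction_lymphocyte": lymph,
        "fraction_monocyte": mono,
        "fraction_granulocyte": gran,
        "malignant_cells_present": group in (Syndrome.TO, Syndrome.TP),
        "it_igg": it[0],
        "it_iga": it[1],
        "it_igm": it[2],
    }, columns=list(COLUMNS))
    frame["group_true"] = g
    frame["ceb"] = ceb
    return frame


def generate_cohort(
    specs: Optional[dict[Syndrome, GroupQuantileSpec]] = None,
    seed: int = 0,
    scale: float = 1.0,
    plumbing: Optional[dict] = None,
) -> SyntheticCohort:
    """Generate the full multi-group cohort (8183 records at scale 1).

    Group sizes are ``round(scale x n)``; the concatenated records are
    shuffled deterministically under the root seed.
    """
    default_specs, default_plumbing = load_default_specs()
    if specs is None:
        specs = default_specs
    if plumbing is None:
        plumbing = default_plumbing
    from .reference import load_reference_table

    table = load_reference_table()
    parts = []
    for group in GROUP_ORDER:
        if group not in specs:
            continue
        spec = specs[group]
        n_g = int(np.round(scale * spec.n))
        if n_g < 1:
            continue
        ceb = sample_ceb(spec, n_g, seed)
        parts.append(realize_group(group, ceb, seed, plumbing, table))
    if not parts:
        raise ValueError("no groups to generate (scale too small?)")
    frame = pd.concat(parts, ignore_index=True)
    perm = _substream(seed, "shuffle").permutation(len(frame))
    frame = frame.iloc[perm].reset_index(drop=True)
    return SyntheticCohort(frame=frame, seed=seed, spec_version=SPEC_VERSION, scale=scale)
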