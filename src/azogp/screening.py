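"""Criterion-based virtual screening of SMILES libraries.

Candidates are scored with a fitted multioutput GP on the two pi-pi*
tasks and judged against two photophysical criteria chosen for materials
and photopharmacology applications:

1. the E-isomer pi-pi* maximum falls in a visible window
   (default 450-600 nm, inclusive at the boundary), limiting UV damage and
   improving tissue penetration; and
2. the E and Z pi-pi* bands are separated by more than a threshold
   (default 40 nm), enabling selective addressing of each isomer with
   broad-emission LEDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gp
from .data import Task
from .evaluation import metric_suite
from .features import DEFAULT_CONFIG, FeatureConfig, featurize_library


@dataclass(frozen=True)
class ScreeningCriteria:
    e_pipi_window: tuple[float, float] = (450.0, 600.0)
    min_separation: float = 40.0
    boundary_inclusive: bool = True
    absolute_separation: bool = False

    def __post_init__(self):
        lo, hi = self.e_pipi_window
        if not lo < hi:
            raise ValueError("window lower bound must be below upper bound")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be > 0")


DEFAULT_CRITERIA = ScreeningCriteria()


@dataclass
class CandidateVerdict:
    smiles: str | None
    pred_e_pipi: float
    pred_z_pipi: float | None
    var_e: float | None = None
    var_z: float | None = None
    passes_c1: bool = False
    passes_c2: bool = False
    passes_both: bool = False
    rank: int | None = None

    @property
    def separation(self) -> float | None:
        if self.pred_z_pipi is None:
            return None
        return self.pred_e_pipi - self.pred_z_pipi


def check_criteria(e_pipi: float, z_pipi: float | None,
                   criteria: ScreeningCriteria = DEFAULT_CRITERIA
                   ) -> tuple[bool, bool, bool]:
    """(passes_c1, passes_c2, passes_both) for one candidate.

    Criterion 2 is False when the Z value is absent — screening stays total
    over a library. Separation is signed (E band red of Z band) unless
    ``absolute_separation`` is set.
    """
    if z_pipi is not None and (isinstance(z_pipi, float)
                               and np.isnan(z_pipi)):
        z_pipi = None
    lo, hi = criteria.e_pipi_window
    if criteria.boundary_inclusive:
        c1 = lo <= e_pipi <= hi
    else:
        c1 = lo < e_pipi < hi
    if z_pipi is None:
        c2 = False
    else:
        sep = e_pipi - z_pipi
        if criteria.absolute_separation:
            sep = abs(sep)
        c2 = sep > criteria.min_separation
    return c1, c2, c1 and c2


def screen_library(mogp_state: gp.MOGPState, smiles_list,
                   criteria: ScreeningCriteria = DEFAULT_CRITERIA,
                   feature_config: FeatureConfig = DEFAULT_CONFIG,
                   mode: str = "fragprints") -> list[CandidateVerdict]:
    """Featurize, predict both pi-pi* bands, apply the criteria and rank.

    Passing candidates come first, ordered by descending predicted E-isomer
    pi-pi* wavelength (most red-shifted first) and then by descending
    predicted band separation; invalid SMILES are skipped with a log entry.
    The returned list covers every valid candidate, with ``rank`` set on
    the passing ones.
    """
    lib = featurize_library(smiles_list, mode=mode, config=feature_config)
    e_mean, e_var = gp.predict_mogp(mogp_state, lib.matrix, Task.E_PI_PI)
    z_mean, z_var = gp.predict_mogp(mogp_state, lib.matrix, Task.Z_PI_PI)
    smiles_list = list(smiles_list)
    verdicts = []
    for row, idx in enumerate(lib.kept_indices):
        c1, c2, both = check_criteria(float(e_mean[row]),
                                      float(z_mean[row]), criteria)
        verdicts.append(CandidateVerdict(
            smiles=str(smiles_list[idx]),
            pred_e_pipi=float(e_mean[row]), pred_z_pipi=float(z_mean[row]),
            var_e=float(e_var[row]), var_z=float(z_var[row]),
            passes_c1=c1, passes_c2=c2, passes_both=both,
        ))
    verdicts.sort(key=lambda v: (
        not v.passes_both,
        -v.pred_e_pipi,
        -(v.separation if v.separation is not None else -np.inf),
    ))
    rank = 0
    for v in verdicts:
        if v.passes_both:
            rank += 1
            v.rank = rank
    return verdicts


@dataclass
class ScreeningReport:
    verdicts: list[CandidateVerdict] = field(default_factory=list)
    mae_e: float = float("nan")
    mae_z: float = float("nan")
    n_e: int = 0
    n_z: int = 0
    count_c1: int = 0
    count_c2: int = 0
    count_both: int = 0
    n_candidates: int = 0


def screening_report(predicted, experimental,
                     criteria: ScreeningCriteria = DEFAULT_CRITERIA
                     ) -> ScreeningReport:
    """Model-vs-experiment summary in the style of a post-screen write-up.

    ``predicted`` is a sequence of (E, Z) model values; ``experimental`` a
    sequence of (E, Z-or-None) measured values. MAEs compare model to
    experiment (candidates lacking an experimental Z are excluded from the
    Z MAE); criteria counts are computed on the EXPERIMENTAL values. MAEs
    are reported to one decimal place in nm.
    """
    predicted = list(predicted)
    experimental = list(experimental)
    if len(predicted) != len(experimental):
        raise ValueError("predicted and experimental lists must align")
    e_report = metric_suite([p[0] for p in predicted],
                            [e[0] for e in experimental])
    z_report = metric_suite([p[1] for p in predicted],
                            [e[1] for e in experimental])
    verdicts = []
    c1_count = c2_count = both_count = 0
    for (pe, pz), (ee, ez) in zip(predicted, experimental):
        c1, c2, both = check_criteria(ee, ez, criteria)
        c1_count += c1
        c2_count += c2
        both_count += both
        verdicts.append(CandidateVerdict(
            smiles=None, pred_e_pipi=pe, pred_z_pipi=pz,
            passes_c1=c1, passes_c2=c2, passes_both=both,
        ))
    return ScreeningReport(
        verdicts=verdicts,
        mae_e=round(e_report.mae, 1), mae_z=round(z_report.mae, 1),
        n_e=e_report.n, n_z=z_report.n,
        count_c1=c1_count, count_c2=c2_count, count_both=both_count,
        n_candidates=len(predicted),
    )
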