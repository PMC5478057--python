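"""msrecap: age-structured multistate mark-recapture analysis.

A toolkit for the four-state (colony x breeding status) mark-recapture
model used in long-term studies of colonial bats: transition-matrix
construction, product-multinomial likelihood fitting, AIC model selection
and averaging, life-history summaries, and a matching simulator.
"""

from importlib import resources

import pandas as pd

from .data_model import (
    ADULT,
    JUVENILE,
    CaptureHistory,
    Dataset,
    DesignError,
    InvalidHistoryError,
    StudyDesign,
    export_inp,
    read_histories,
    read_inp,
    summarize,
    validate_history,
    write_histories,
)
from .model_spec import (
    ModelSpec,
    ParameterIndex,
    SpecError,
    build_parameter_index,
    invlink,
    link,
    parse_formula,
    parse_model,
)
from .transitions import (
    RateError,
    RateSet,
    TransitionBlock,
    block_for,
    block_kind,
    experienced_block,
    experienced_matrix,
    immature_block,
    immature_matrix,
    juvenile_block,
    juvenile_matrix,
)
from .likelihood import (
    FittedModel,
    ImpossibleHistoryError,
    dataset_deviance,
    dataset_nll,
    fit,
    history_nll,
    pool_dataset,
    pooled_nll,
)
from .selection import ModelRecord, ModelSet, model_average, rank
from .derived import (
    LifeHistorySummary,
    geometric_mean,
    life_expectancy,
    mean_age_first_reproduction,
    reproductive_years,
    species_summary,
)
from .simulate import (
    BLYTHII,
    MYOTIS,
    SimulationConfig,
    mouse_eared_study_config,
    simulate,
    study_design,
    study_rateset,
)

__version__ = "0.1.0"

_REFERENCE_TABLES = {
    "survival": "survival_model_table.tsv",
    "cockchafer_survival": "cockchafer_survival_table.tsv",
    "first_breeding_cockchafer": "first_breeding_cockchafer_table.tsv",
}


def load_reference_table(name: str) -> pd.DataFrame:
    """Published model-selection tables from the 13-year mouse-eared bat
    study (model label, deviance, parameter count, ΔAIC, Akaike weight).

    Names: ``survival``, ``cockchafer_survival``,
    ``first_breeding_cockchafer``.
    """
    fname = _REFERENCE_TABLES[name]
    with resources.files(__package__).joinpath("data", fname).open() as fh:
        return pd.read_csv(fh, sep="\t")
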