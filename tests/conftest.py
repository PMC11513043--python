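import warnings

import numpy as np
import pandas as pd
import pytest

from exocnv.simulate import SimConfig, CohortSimulator
from exocnv.preprocess import CoveragePreprocessor, remove_gc_extreme_targets
from exocnv.clincnv import ClinCnvCaller
from exocnv.conifer import ConiferCaller
from exocnv.exomedepth import ExomeDepthCaller

warnings.filterwarnings("ignore", category=FutureWarning)


def make_targets(rows):
    """Targets frame from (chrom, start, end, gc) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])
    df["kit_id"] = "KIT1"
    df.index = pd.Index(
        df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-" + df["end"].astype(str),
        name="target_id")
    return df


@pytest.fixture(scope="session")
def cohort():
    """A mid-size simulated cohort shared by module tests."""
    return CohortSimulator(SimConfig(targets_per_kit=1500, samples_per_kit=80, seed=11)).run()


@pytest.fixture(scope="session")
def preprocessed(cohort):
    kit = cohort.kits["KIT1"]
    return CoveragePreprocessor().fit_transform_cohort(kit.counts, kit.targets, cohort.samples)


@pytest.fixture(scope="session")
def clincnv_fit(cohort, preprocessed):
    caller = ClinCnvCaller()
    caller.fit(preprocessed.matrix, windows=preprocessed.windows, samples=preprocessed.samples)
    return caller


@pytest.fixture(scope="session")
def clincnv_calls(clincnv_fit):
    return clincnv_fit.predict()


@pytest.fixture(scope="session")
def acceptance_run():
    """The full study-scale cohort (100 samples x 5000 targets) with all
    three callers, shared by the acceptance checks."""
    cohort = CohortSimulator(SimConfig(targets_per_kit=5000, samples_per_kit=100, seed=0)).run()
    kit = cohort.kits["KIT1"]
    pre = CoveragePreprocessor().fit_transform_cohort(kit.counts, kit.targets, cohort.samples)
    clin = ClinCnvCaller().fit_predict(pre.matrix, windows=pre.windows, samples=pre.samples)
    kept, _ = remove_gc_extreme_targets(kit.targets)
    counts = kit.counts.loc[kept.index]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        con = ConiferCaller().fit_predict(counts, targets=kept, samples=cohort.samples)
        ed = ExomeDepthCaller().fit_predict(counts, targets=kept, samples=cohort.samples)
    pooled = pd.concat([clin, con, ed], ignore_index=True)
    return dict(cohort=cohort, pre=pre, clincnv=clin, conifer=con, exomedepth=ed,
                pooled=pooled)


def truth_window_span(truth_row, windows):
    """Number of surviving coverage windows inside a truth interval."""
    m = ((windows["chrom"] == truth_row["chrom"])
         & (windows["start"] >= truth_row["start"])
         & (windows["start"] < truth_row["end"]))
    return int(m.sum())


def found(calls, ev, cnv_type=None):
    m = ((calls["sample_id"] == ev["sample_id"]) & (calls["chrom"] == ev["chrom"])
         & (calls["start"] < ev["end"]) & (ev["start"] < calls["end"]))
    if cnv_type is not None:
        m &= calls["type"] == cnv_type
    return bool(m.any())
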