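import numpy as np
import pandas as pd
import pytest

import tp53cistrome as t
from tp53cistrome import motif_model as mm


@pytest.fixture(scope="session")
def tetramer():
    return t.tp53_tetramer_pwm()


@pytest.fixture(scope="session")
def small_screen():
    """A modest simulated screen shared across reporter tests."""
    cfg = t.SimConfig(n_regions=200, seed=2)
    regions, truth = t.synth_data.simulate_regions(cfg)
    library = t.synth_data.simulate_library(truth, cfg)
    counts, samples = t.synth_data.simulate_counts(library, truth, cfg)
    return cfg, regions, truth, library, counts, samples


def run_activity_pipeline(cfg):
    """Simulate -> couple -> normalise -> call; returns (calls, truth)."""
    _, truth = t.synth_data.simulate_regions(cfg)
    library = t.synth_data.simulate_library(truth, cfg)
    counts, samples = t.synth_data.simulate_counts(library, truth, cfg)
    couplings = t.build_coupling_dictionary(library)
    normalized, low = t.normalize_counts(counts, samples)
    calls = t.call_activity(normalized, couplings, samples, low_coverage=low)
    return calls, truth


def recovery_rates(calls, truth):
    """(sensitivity, fpr) of the positive class against planted truth."""
    truth_cls = pd.Series(truth.region_class)
    merged = calls.set_index("region_id").join(truth_cls.rename("truth"))
    merged = merged[merged["class"] != "low_coverage"]
    resp = merged["truth"] == "responsive"
    sens = ((merged["class"] == "positive") & resp).sum() / max(resp.sum(), 1)
    fpr = ((merged["class"] == "positive") & ~resp).sum() / max((~resp).sum(), 1)
    return float(sens), float(fpr)


def planted_feature_frame(cfg, pwms):
    """Feature matrix + direct/indirect labels from a planted-motif sim."""
    regions, truth = t.synth_data.simulate_regions(cfg)
    X = pd.DataFrame(mm.feature_matrix(pwms, [s for _, s in regions]),
                     columns=[p.name for p in pwms],
                     index=[r for r, _ in regions])
    y = np.array(["direct" if truth.region_class[r] == "responsive"
                  else "indirect" for r, _ in regions])
    return X, y, truth
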