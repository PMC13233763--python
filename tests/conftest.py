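import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from glytrace.core_io import CtTable, FeatureTable, SampleMeta


@pytest.fixture
def tiny_meta() -> SampleMeta:
    """Two cell models x (control + one condition) x 2 replicates."""
    rows = []
    for model in ("HepG2", "HLC_d44"):
        for cond, src, dose in (("HBSS", "none", None), ("GLY20", "GLY", 20.0)):
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{model}_{cond}_r{rep}",
                        "cell_model": model,
                        "condition": cond,
                        "carbon_source": src,
                        "dose_mM": dose,
                        "replicate": rep,
                        "batch": "B1",
                        "dna_ug": 2.0,
                        "cell_count": 100_000,
                    }
                )
    return SampleMeta(pd.DataFrame(rows))


@pytest.fixture
def tiny_features(tiny_meta) -> FeatureTable:
    rng = np.random.default_rng(0)
    mets = ["ATP", "citrate", "glycine"]
    samples = tiny_meta.sample_ids
    analyte = pd.DataFrame(
        rng.uniform(1e4, 1e6, size=(len(mets), len(samples))), index=mets, columns=samples
    )
    is_chan = pd.DataFrame(
        rng.uniform(1e3, 1e5, size=(len(mets), len(samples))), index=mets, columns=samples
    )
    return FeatureTable(analyte, is_chan)


def make_ct_table(rows) -> CtTable:
    return CtTable(pd.DataFrame(rows, columns=["gene", "sample_id", "plate_id", "ct", "is_calibrator"]))
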