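import numpy as np
import pandas as pd
import pytest

from bcfdna import synthetic_data as sd
from bcfdna.targets import AmpliconTarget, TargetPanel, build_default_panel


@pytest.fixture(scope="session")
def panel() -> TargetPanel:
    return build_default_panel()


@pytest.fixture(scope="session")
def profiles(panel):
    return sd.default_tissue_profiles(panel)


@pytest.fixture(scope="session")
def toy_target() -> AmpliconTarget:
    """A tiny 4-CpG amplicon with no primer CpGs, for hand-traceable cases."""
    #         0         1         2         3         4         5
    #         0123456789012345678901234567890123456789012345678901234567
    seq = "ATGATTAAGGACGATACGATTAGGATACGATTAACGATTAGGATTAATAGGATTAAAT"
    return AmpliconTarget(
        name="toy",
        reference_sequence=seq,
        fwd_primer="ATGATTAAGG",
        rev_primer="GGATTAAAT",
        cpg_offsets=(11, 16, 27, 34),
        brain_epihap_direction="all-unmethylated",
    )


@pytest.fixture()
def toy_calls() -> pd.DataFrame:
    """The worked filtering fixture: counts {000: 5, 111: 3, 012: 2, 101: 1}."""
    strings = ["000"] * 5 + ["111"] * 3 + ["012"] * 2 + ["101"]
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(strings))],
            "sample_id": "S1",
            "target": "T1",
            "call_string": strings,
        }
    )


@pytest.fixture(scope="session")
def validation_cohort(panel, profiles):
    """A 6 brain + 14 non-brain cohort of epihaplotype tables (depth 2000)."""
    from bcfdna.amplicon_caller import call_reads
    from bcfdna.epihaplotype import filter_and_count, trim_panel

    brain_prof, other_prof = profiles
    cfg = sd.ReadSimConfig(depth_per_target=2000, seed=11)
    calls = []
    meta = []
    for i in range(20):
        is_brain = i < 6
        sid = f"{'BR' if is_brain else 'OT'}{i:02d}"
        meta.append({"sample_id": sid, "is_brain": is_brain})
        for t in panel:
            batch, _ = sd.simulate_reads(
                t, brain_prof if is_brain else other_prof, cfg, sample_id=sid
            )
            calls.append(call_reads(batch, panel).calls)
    calls = trim_panel(pd.concat(calls, ignore_index=True), panel)
    table = filter_and_count(calls)
    return table, pd.DataFrame(meta)
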