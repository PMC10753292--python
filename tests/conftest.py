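import pathlib

import pandas as pd
import pytest

from splicequant import quantify, simdata


@pytest.fixture(scope="session")
def simple_ir_run(tmp_path_factory):
    """A processed 3v3 retained-intron experiment (PSI 0.2 vs 0.4, 60x)."""
    work = pathlib.Path(tmp_path_factory.mktemp("simple_ir_run"))
    depth = 60.0
    ab = {}
    for i in (1, 2, 3):
        ab[f"A{i}"] = {"retained": depth * 0.2, "spliced": depth * 0.8}
        ab[f"B{i}"] = {"retained": depth * 0.4, "spliced": depth * 0.6}
    scenario = simdata.make_scenario("simple_ir", abundances=ab, seed=101)
    ref = scenario.build_reference(work / "ref")
    bams = simdata.simulate_reads(scenario, work / "sim", seed=101)
    bundles = [
        quantify.process_sample(bam, ref, work / "proc" / sid, sample_id=sid,
                                protocol="unstranded")
        for sid, bam in bams.items()
    ]
    info = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3},
                        index=pd.Index(sorted(bams), name="sample_id"))
    x = quantify.collate(bundles, ref, work / "exp", sample_info=info)
    return {"scenario": scenario, "ref": ref, "bams": bams, "bundles": bundles,
            "experiment": x, "work": work}


@pytest.fixture(scope="session")
def multi_isoform_ref(tmp_path_factory):
    """Reference for the seven-transcript multi-isoform locus."""
    work = pathlib.Path(tmp_path_factory.mktemp("multi_iso"))
    scenario = simdata.make_scenario("fig_multi_isoform", seed=5)
    return scenario, scenario.build_reference(work / "ref")
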