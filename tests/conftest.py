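from dataclasses import replace

import pytest

from musemo.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default study conditions."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(seed=1)
    report = run_all(cfg, out)
    return out, cfg, report


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Pipeline run with ground truth carried purely by one channel per
    dimension (valence: audio only; arousal: physiology only) at low noise."""
    out = tmp_path_factory.mktemp("recovery_run")
    cfg = PipelineConfig(seed=7)
    cfg.generator = replace(cfg.generator, mixing_valence=(1.0, 0.0),
                            mixing_arousal=(0.0, 1.0), rating_noise_sd=0.05)
    report = run_all(cfg, out)
    return out, cfg, report
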