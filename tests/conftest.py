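import pandas as pd
import pytest
import yaml

from otolith_origin.calibration import CalibrationModel
from otolith_origin.config import default_scenario, noise_free_scenario
from otolith_origin.pipeline import RunConfig, run_pipeline


class PipelineRun:
    """Loaded outputs of one full pipeline run."""

    def __init__(self, out_dir, scenario):
        self.out_dir = str(out_dir)
        self.scenario = scenario
        self.water = pd.read_csv(f"{out_dir}/water.csv")
        self.fish = pd.read_csv(f"{out_dir}/fish.csv")
        self.truth = pd.read_csv(f"{out_dir}/truth.csv")
        self.summaries = pd.read_csv(f"{out_dir}/summaries.csv")
        self.windows = pd.read_csv(f"{out_dir}/windows.csv")
        self.assignments = pd.read_csv(f"{out_dir}/assignments.csv")
        self.tests = pd.read_csv(f"{out_dir}/tests.csv")
        with open(f"{out_dir}/calibration.yaml") as fh:
            self.models = {
                fam: CalibrationModel.from_dict(d)
                for fam, d in yaml.safe_load(fh).items()
            }
        self.bodies = {wb.id: wb for wb in scenario.water_bodies}

    def classified(self):
        """Non-reference, non-vateritic assignments joined to truth."""
        df = self.assignments.merge(
            self.truth[["fish_id", "natal_body", "core_srca_noise_free", "vaterite"]],
            on="fish_id",
        )
        return df[(df["source"] != "reference") & (~df["vaterite"].astype(bool))]


def run_scenario(tmp_dir, scenario, seed):
    cfg = RunConfig(out_dir=str(tmp_dir), seed=seed, scenario=scenario)
    run_pipeline(cfg)
    return PipelineRun(tmp_dir, scenario)


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory):
    d = tmp_path_factory.mktemp("noise_free")
    return run_scenario(d, noise_free_scenario(1), seed=1)


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    d = tmp_path_factory.mktemp("noisy")
    return run_scenario(d, default_scenario(1), seed=1)
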