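import pytest

from fieldcenter import BisectionParams, GroupSummary
from fieldcenter.fitting import predicted_summaries
from fieldcenter.simulate import exp1_conditions, exp2_conditions

# fitted parameter sets the noiseless round-trip exercises (SI units)
EXP1_PARAMS = BisectionParams(F_th=0.085, sigma_Fth=0.052,
                              sigma_P_fp=0.0093, sigma_P_fa=0.012)
EXP2_PARAMS = BisectionParams.unilateral(F_th=0.12, sigma_F=0.062,
                                         sigma_P=0.0051)


def noiseless_summaries(experiment: str,
                        params: BisectionParams) -> list[GroupSummary]:
    """Group summaries that equal the model's own predictions exactly."""
    conds = exp1_conditions() if experiment == "exp1" else exp2_conditions()
    preds = predicted_summaries(conds, params)
    return [GroupSummary(c, mu, 0.0, sd, 12)
            for c, (mu, sd) in zip(conds, preds)]


@pytest.fixture(scope="session")
def exp1_noiseless():
    return noiseless_summaries("exp1", EXP1_PARAMS)


@pytest.fixture(scope="session")
def exp2_noiseless():
    return noiseless_summaries("exp2", EXP2_PARAMS)
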