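"""Named simulation designs shared across the test suite.

The step design is simply the generator's default configuration (full
emulated baseline table, tau = -0.06 for chronic hypertension, -0.02
otherwise).  The other designs strip the problem down to what each study
needs: a clearly detectable modifier for retention studies, a homogeneous
effect for null calibration, and a smooth effect surface for coverage.
"""

from trialhte.simulate import (CovariateSpec, FunctionDescriptor,
                               SimulationConfig)


def step_design(n: int, seed: int) -> SimulationConfig:
    """Default generator: step CATE on chronic hypertension (-0.06 / -0.02)."""
    return SimulationConfig(n=n, seed=seed)


def smooth_design(n: int, seed: int) -> SimulationConfig:
    """Smooth CATE in the physiology score, extra benefit with hypertension."""
    return SimulationConfig(n=n, seed=seed,
                            cate_fn=FunctionDescriptor("smooth"))


def homogeneous_design(n: int, seed: int, tau: float = -0.03
                       ) -> SimulationConfig:
    """Constant treatment effect (null heterogeneity)."""
    return SimulationConfig(n=n, seed=seed,
                            cate_fn=FunctionDescriptor("constant",
                                                       {"tau": tau}))


def modifier_noise_design(n: int, seed: int, tau_in: float = -0.25,
                          tau_out: float = 0.0) -> SimulationConfig:
    """One binary effect modifier plus 8 pure-noise covariates.

    The modifier's effect is made large enough to be clearly detectable so
    the study isolates the filtering/importance machinery rather than raw
    statistical power.
    """
    spec = [CovariateSpec("modifier", "binary", {"p": 0.5})]
    spec += [CovariateSpec(f"noise_c{i}", "continuous",
                           {"dist": "normal", "mean": 0.0, "sd": 1.0})
             for i in range(4)]
    spec += [CovariateSpec(f"noise_b{i}", "binary", {"p": 0.3})
             for i in range(4)]
    return SimulationConfig(
        n=n, seed=seed, covariate_spec=spec,
        baseline_risk=FunctionDescriptor("constant", {"p": 0.45}),
        cate_fn=FunctionDescriptor("step", {"var": "modifier",
                                            "tau_in": tau_in,
                                            "tau_out": tau_out}))
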