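"""Search configuration shared by the fitness evaluation and the GA."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class SearchConfig:
    """Knobs of the knockout search.

    Attributes
    ----------
    k_max
        Maximum knockouts per design (genome length).
    pop_size
        Population size; must be even and >= 4.
    mutation_rate
        Per-slot reset probability; ``None`` defaults to ``1 / k_max``.
    crossover_prob
        Probability a parent pair undergoes uniform crossover.
    time_limit
        Wall-clock budget in seconds.
    max_generations, stall_generations, stall_tol
        Generation cap and hypervolume-stall termination: stop when the
        relative hypervolume change over ``stall_generations``
        generations falls below ``stall_tol``.
    seed
        RNG seed; a fixed seed makes the whole run deterministic.
    tau
        Relative growth tolerance when reading off guaranteed synthesis
        at maximum growth (floor = (1 - tau) * mu*).
    eps_p
        Product flux below this counts as no synthesis (mmol/gDW/h).
    f_min
        Fraction of mu* above which the lower envelope must be positive
        for a design to count as strongly coupled.
    n_env
        Production envelope grid resolution (n+1 points).
    min_growth_frac
        Designs growing below this fraction of wild-type mu* are
        non-viable; also the growth-essentiality screen threshold.
    solver
        LP backend identifier passed to scipy (``highs``,
        ``highs-ds``, ``highs-ipm``).
    cs_functional
        Name of the coupling-strength functional (``envelope-area`` is
        the built-in default; alternatives can be registered).
    """

    k_max: int = 3
    pop_size: int = 200
    mutation_rate: float | None = None
    crossover_prob: float = 0.8
    time_limit: float = 3600.0
    max_generations: int = 1000
    stall_generations: int = 50
    stall_tol: float = 1e-4
    seed: int = 0
    tau: float = 1e-3
    eps_p: float = 1e-4
    f_min: float = 0.1
    n_env: int = 10
    min_growth_frac: float = 0.01
    solver: str = "highs"
    cs_functional: str = "envelope-area"

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 4")
        if self.mutation_rate is None:
            self.mutation_rate = 1.0 / self.k_max
        for name in ("mutation_rate", "crossover_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)
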