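"""Run configurations: model + alchemical layout + schedule, YAML round-trip.

A :class:`RunConfig` is declarative — the potential model is referenced by
registry name plus parameters, so configurations serialize to plain YAML and
rebuild deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .lambda_states import LambdaStateGraph, build_multisite_graph, build_single_site_graph
from .potentials import PotentialModel, build_model
from .sampler import GibbsSchedule

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one LaDyBUGS calculation.

    ``substituent_counts`` gives the alchemical layout (one entry per site);
    a single-entry list is the single-site all-pairs layout.  ``flat_bias``
    (B, kcal/mol) and ``eps_b`` (ε_b, kcal/mol) parameterize the two-phase
    dynamic bias.
    """

    model_name: str
    model_params: dict
    substituent_counts: list[int]
    delta_lambda: float
    schedule: GibbsSchedule
    reference_ligand: int | list[int] = 0
    flat_bias: float = 100.0
    eps_b: float = 1.0
    include_env_in_energies: bool = False
    n_boot: int = 100
    label: str = ""

    def build_model(self) -> PotentialModel:
        return build_model(self.model_name, self.model_params)

    def build_graph(self) -> LambdaStateGraph:
        if len(self.substituent_counts) == 1:
            return build_single_site_graph(
                self.substituent_counts[0],
                self.delta_lambda,
                reference_ligand=int(self.reference_ligand)
                if not isinstance(self.reference_ligand, (list, tuple))
                else int(self.reference_ligand[0]),
            )
        ref = self.reference_ligand
        if isinstance(ref, int):
            ref = [0] * len(self.substituent_counts)
        return build_multisite_graph(
            self.substituent_counts, self.delta_lambda, reference_ligand=tuple(ref)
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = asdict(self.schedule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["schedule"] = GibbsSchedule(**d["schedule"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))
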