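"""The computational phenotype: posterior point estimates per session.

A :class:`PhenotypeMatrix` holds one posterior-mean estimate per
(participant, week, task, parameter). Weeks with no data carry no row —
they are never silently imputed; :meth:`PhenotypeMatrix.matrix` exposes
them as NaN cells for downstream complete-case filtering.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .hier.fit import HierarchicalFit, convergence_diagnostics
from .tasks import get_model
from .transforms import get_transform

__all__ = ["PhenotypeMatrix", "to_phenotype_matrix"]


@dataclasses.dataclass
class PhenotypeMatrix:
    """Long-format point estimates of the phenotype."""

    df: pd.DataFrame  # participant_id, week, task, parameter, estimate, space

    def matrix(self, task: str, parameter: str) -> pd.DataFrame:
        """Participants x weeks wide matrix (NaN where a week is missing)."""
        d = self.df[(self.df["task"] == task) & (self.df["parameter"] == parameter)]
        return d.pivot(index="participant_id", columns="week", values="estimate")

    def save(self, path) -> None:
        self.df.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def load(cls, path) -> "PhenotypeMatrix":
        return cls(df=pd.read_csv(path, na_values=["NA"], keep_default_na=False))


def to_phenotype_matrix(
    fit: HierarchicalFit,
    constrained: bool = True,
    override: bool = False,
    rhat_max: float = 1.01,
) -> PhenotypeMatrix:
    """Posterior mean per (participant, week, parameter) from one fit.

    Refuses on failed convergence diagnostics unless ``override`` is set.
    Constrained-space estimates are means of the transformed draws.
    """
    report = convergence_diagnostics(fit, rhat_max=rhat_max)
    if not report["pass"] and not override:
        raise RuntimeError(f"convergence diagnostics failed: {report}")
    m = get_model(fit.task)
    y = fit.flat("y")  # (draws, n_obs, P)
    rows = []
    for j, pname in enumerate(fit.param_names):
        tr = get_transform(m.TRANSFORM_NAMES[j])
        est = (tr.constrain(y[:, :, j]) if constrained else y[:, :, j]).mean(axis=0)
        for i in range(fit.obs.n_obs):
            rows.append(
                dict(
                    participant_id=fit.obs.participant_ids[fit.obs.part_idx[i]],
                    week=int(fit.obs.week[i]),
                    task=fit.task,
                    parameter=pname,
                    estimate=float(est[i]),
                    space="constrained" if constrained else "unconstrained",
                )
            )
    return PhenotypeMatrix(df=pd.DataFrame(rows))
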