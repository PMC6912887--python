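"""Posterior results container for fitted age-structured CJS models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .sampling import MCMCConfig, PosteriorSummary

__all__ = ["CJSResults"]


@dataclass
class CJSResults:
    """Retained posterior draws and summaries from one MCMC run.

    Attributes
    ----------
    model : AgeStructuredCJS
        The fitted model.
    mcmc : MCMCConfig
        Chain protocol used.
    theta_draws : ndarray, shape (n_chains, n_draws, d)
        Retained draws on the unconstrained scale.
    draws : dict of str -> ndarray (n_chains, n_draws)
        Retained draws of the named constrained parameters.
    posterior_summary : PosteriorSummary
        Means, SDs, credible intervals and diagnostics.
    """

    model: object
    mcmc: MCMCConfig
    theta_draws: np.ndarray
    draws: Dict[str, np.ndarray]
    posterior_summary: PosteriorSummary

    # ------------------------------------------------------------------
    @property
    def converged(self) -> bool:
        return self.posterior_summary.converged

    @property
    def rho_mean(self) -> float:
        return float(self.posterior_summary["rho"]["mean"])

    @property
    def rho_cri(self) -> Tuple[float, float]:
        row = self.posterior_summary["rho"]
        return float(row["q2.5"]), float(row["q97.5"])

    def posterior(self, name: str) -> np.ndarray:
        """Pooled retained draws of one named parameter."""
        return np.asarray(self.draws[name]).reshape(-1)

    # ------------------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior summary table (mean, sd, 2.5/50/97.5%, R-hat, ESS)."""
        return self.posterior_summary.table

    def __str__(self) -> str:
        meta = self.posterior_summary.metadata
        lines = [
            "Age-structured CJS model - posterior summary",
            f"  sampler={meta.get('sampler')}  chains={meta.get('n_chains')}"
            f"  retained draws={meta.get('n_retained')}"
            f"  seed={meta.get('seed')}",
        ]
        if not self.converged:
            lines.append(
                "  WARNING: R-hat > 1.1 for "
                + ", ".join(meta.get("nonconverged_parameters", []))
            )
        with pd.option_context("display.width", 120):
            lines.append(self.summary().round(4).to_string())
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def draws_frame(self) -> pd.DataFrame:
        """Pooled retained draws, one column per named parameter."""
        return pd.DataFrame({k: v.reshape(-1) for k, v in self.draws.items()})

    def export_draws(self, path) -> None:
        self.draws_frame().to_csv(path, index=False)

    def export_summary(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.posterior_summary.to_json())
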