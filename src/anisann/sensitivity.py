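"""Connection-weight (Yoon) global sensitivity of a trained network.

The relative importance of input i on output j is computed from the two
weight matrices only (biases are excluded):

    RI_ij(%) = Σ_k (w_ik · w_kj)  /  Σ_i |Σ_k (w_ik · w_kj)|  × 100

where k runs over hidden units.  The denominator sums over inputs, so within
every output column the absolute importances total 100% and the sign carries
the direction of influence.  The measure is invariant to a positive global
rescaling of either weight matrix, but *not* to per-input rescaling of the
first-layer weights — importances are therefore computed on the weight scale
the network was trained on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RelativeImportanceMatrix", "yoon_relative_importance", "rank_influences"]


@dataclass
class RelativeImportanceMatrix:
    """Signed percentage influence of each input (rows) on each output (columns).

    ``degenerate`` flags outputs whose connection-weight products are all
    zero; their columns are NaN.
    """

    RI: np.ndarray
    input_names: list[str]
    output_names: list[str]
    degenerate: np.ndarray

    def column(self, output_name: str) -> np.ndarray:
        try:
            j = self.output_names.index(output_name)
        except ValueError:
            raise KeyError(f"unknown output name: {output_name!r}") from None
        return self.RI[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Wide export: inputs as rows, outputs as columns."""
        df = pd.DataFrame(self.RI, index=self.input_names, columns=self.output_names)
        df.index.name = "input"
        return df

    def to_long_frame(self) -> pd.DataFrame:
        """Long export (input, output, ri_percent) for importance-bar plots."""
        df = self.to_frame().reset_index().melt(
            id_vars="input", var_name="output", value_name="ri_percent"
        )
        return df


def yoon_relative_importance(
    W1: np.ndarray,
    W2: np.ndarray,
    input_names: list[str] | None = None,
    output_names: list[str] | None = None,
) -> RelativeImportanceMatrix:
    """Connection-weight relative importances from the two weight matrices.

    Parameters
    ----------
    W1 : ndarray, inputs × hidden
        Input-to-hidden weights.
    W2 : ndarray, hidden × outputs
        Hidden-to-output weights.  ``W1.shape[1]`` must equal ``W2.shape[0]``.
    """
    W1 = np.asarray(W1, dtype=float)
    W2 = np.asarray(W2, dtype=float)
    if W1.ndim != 2 or W2.ndim != 2 or W1.shape[1] != W2.shape[0]:
        raise ValueError(
            f"hidden dimensions disagree: W1 {W1.shape}, W2 {W2.shape}"
        )
    numerators = W1 @ W2                       # Σ_k w_ik·w_kj, inputs × outputs
    denom = np.abs(numerators).sum(axis=0)
    degenerate = denom == 0.0
    safe = np.where(degenerate, 1.0, denom)
    RI = numerators / safe * 100.0
    RI[:, degenerate] = np.nan
    n_in, n_out = numerators.shape
    return RelativeImportanceMatrix(
        RI=RI,
        input_names=list(input_names) if input_names else [f"input_{i}" for i in range(n_in)],
        output_names=list(output_names) if output_names else [f"output_{j}" for j in range(n_out)],
        degenerate=degenerate,
    )


def rank_influences(
    ri: RelativeImportanceMatrix, output_name: str
) -> list[tuple[str, float]]:
    """Inputs ranked by |RI| (descending) for one output.

    Ties keep input order; a degenerate output returns an empty list.
    """
    col = ri.column(output_name)
    j = ri.output_names.index(output_name)
    if ri.degenerate[j]:
        return []
    order = np.argsort(-np.abs(col), kind="stable")
    return [(ri.input_names[i], float(col[i])) for i in order]
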