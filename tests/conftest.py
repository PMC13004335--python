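from __future__ import annotations

import pandas as pd
import pytest

LIANA_HEADER = (
    "source,target,ligand_complex,receptor_complex,"
    "lr_means,cellphone_pvals,cellchat_pvals"
)


def liana_csv(path, rows):
    """Write a LIANA-named CSV from (src, tgt, lig, rec, mean, pa, pb) rows."""
    lines = [LIANA_HEADER]
    lines += [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def small_table(tmp_path):
    return liana_csv(
        tmp_path / "state.csv",
        [
            ("Fibroblast", "Fibroblast", "FBLN1", "ITGB1", 2.5, 0.01, 0.02),
            ("Fibroblast", "Tcell", "COL1A1", "ITGB1", 1.1, 0.02, 0.01),
            ("Tcell", "Fibroblast", "TGFB1", "TGFBR1", 0.8, 0.03, 0.04),
        ],
    )


def canonical_frame(rows, state="s"):
    """Canonical state table from (src, tgt, lig, rec, mean, pa, pb) rows."""
    return pd.DataFrame(
        [(*row, state) for row in rows],
        columns=[
            "source", "target", "ligand", "receptor", "lr_mean",
            "pval_cellphone", "pval_cellchat", "state",
        ],
    )
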