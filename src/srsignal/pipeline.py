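"""End-to-end orchestration: screen → sex subgroup → Weibull time-to-onset.

A single declarative YAML config names the database tables, the PT→HLT
term map, the target drugs and event groups, and the decision thresholds;
:func:`run_full_analysis` then emits three fixed-format CSVs (the signal
screen, the subgroup contrast, and the Weibull onset table) plus a run log.
Reruns with an identical config and seed are byte-identical.  Every number
in the outputs is produced by the library operations — the orchestration
does no arithmetic of its own.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .bcpnn import SignalThresholds, run_signal_screen, screen_to_frame
from .report_store import Dialect, TermMap, load_database, restrict_to_suspect
from .subgroup import run_subgroup_screen, subgroup_to_frame
from .weibull import extract_tto, fit_weibull, tto_to_frame, WeibullFit

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultBundle", "run_full_analysis"]


class RunConfig(BaseModel):
    demo_path: Path
    drug_path: Path
    reac_path: Path
    hist_path: Optional[Path] = None
    term_map_path: Path
    drugs: list[str] = Field(min_length=1)
    hlts: list[str] = Field(min_length=1)
    signal_lower: float = 1.0
    inverse_upper: float = 0.0
    credible_level: float = 0.95
    interval_method: str = "closed_form"
    weibull_min_n: int = 5
    weibull_all_pairs: bool = False  # fit every pair, not only signal pairs
    seed: int = 0
    output_dir: Path = Path("results")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def thresholds(self) -> SignalThresholds:
        return SignalThresholds(self.signal_lower, self.inverse_upper,
                                self.credible_level)


class ResultBundle(BaseModel):
    model_config = {"arbitrary_types_allowed": True}

    signals_path: Path
    subgroup_path: Path
    tto_path: Path
    log_path: Path


def run_full_analysis(config: RunConfig, dialect: Dialect = Dialect()) -> ResultBundle:
    """Run the three-stage analysis and write its fixed-format outputs.

    Stage failures abort with a stage-named error and partial outputs are
    removed, so an output directory never holds a half-finished run.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = ResultBundle(
        signals_path=outdir / "signal_screen.csv",
        subgroup_path=outdir / "sex_subgroup.csv",
        tto_path=outdir / "weibull_tto.csv",
        log_path=outdir / "run_log.txt",
    )
    written: list[Path] = []
    rng = np.random.default_rng(config.seed)
    try:
        try:
            table_paths = {"demo": config.demo_path, "drug": config.drug_path,
                           "reac": config.reac_path}
            if config.hist_path is not None:
                table_paths["hist"] = config.hist_path
            db = restrict_to_suspect(load_database(table_paths, dialect))
            term_map = TermMap.from_csv(config.term_map_path, dialect)
        except Exception as exc:
            raise RuntimeError(f"stage 'load' failed: {exc}") from exc

        try:
            screen = run_signal_screen(db, config.drugs, config.hlts, term_map,
                                       config.thresholds(),
                                       method=config.interval_method, rng=rng)
            screen_df = screen_to_frame(screen)
            screen_df.to_csv(paths.signals_path, index=False)
            written.append(paths.signals_path)
        except Exception as exc:
            raise RuntimeError(f"stage 'screen' failed: {exc}") from exc

        try:
            subgroup = run_subgroup_screen(db, config.drugs, config.hlts, term_map,
                                           config.credible_level,
                                           method=config.interval_method, rng=rng)
            subgroup_to_frame(subgroup).to_csv(paths.subgroup_path, index=False)
            written.append(paths.subgroup_path)
        except Exception as exc:
            raise RuntimeError(f"stage 'subgroup' failed: {exc}") from exc

        try:
            fits: list[WeibullFit] = []
            for res in screen:
                if res.classification != "signal" and not config.weibull_all_pairs:
                    continue
                sample = extract_tto(db, res.drug, term_map, res.event_group)
                if sample.n_used == 0 and res.observed_o == 0:
                    fits.append(WeibullFit.unavailable(res.drug, res.event_group, 0))
                    continue
                fits.append(fit_weibull(sample, min_n=config.weibull_min_n))
            tto_to_frame(fits).to_csv(paths.tto_path, index=False)
            written.append(paths.tto_path)
        except Exception as exc:
            raise RuntimeError(f"stage 'weibull' failed: {exc}") from exc

        n_signals = sum(r.classification == "signal" for r in screen)
        summary = db.summary()
        with open(paths.log_path, "w") as fh:
            fh.write(f"srsignal {__version__}\n")
            fh.write(f"seed: {config.seed}\n")
            fh.write(f"interval method: {config.interval_method}\n")
            fh.write(f"thresholds: signal IC025 > {config.signal_lower}, "
                     f"inverse IC975 < {config.inverse_upper}\n")
            fh.write(f"n_reports: {db.n_reports}\n")
            for _, row in summary.iterrows():
                fh.write(f"{row['table']}: {row['n_rows']} rows, "
                         f"missing rate {row['missing_rate']:.3f}\n")
            fh.write(f"pairs screened: {len(screen)}; signals: {n_signals}\n")
            for f in fits:
                fh.write(f"weibull {f.drug} x {f.event_group}: n_used={f.n_used} "
                         f"pattern={f.pattern}\n")
        written.append(paths.log_path)
        return paths
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
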