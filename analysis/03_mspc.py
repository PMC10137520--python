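"""Monitoring charts: NOC calibration, T²/Q limits, restart detection.

Splits each stop-free period 65/35 in time (calibration first, mimicking
continuous monitoring), fits a 4-component model on the calibration part
and projects everything else.  The chart table and fitted model go to
``results/mspc/``.  The five planted restart episodes should appear as five
contiguous flagged groups on both charts, while in-control test points stay
inside the nominal 5%.
"""

from pathlib import Path

from procmon.pipeline import RunConfig, run_pipeline
from procmon.synthetic import CampaignConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "mspc"

if __name__ == "__main__":
    report = run_pipeline(
        RunConfig(stage="mspc", campaign=CampaignConfig(), out_dir=OUT, seed=2020)
    )
    s = report.summary
    print(f"calibration {s['n_calibration']} / test {s['n_test']}; "
          f"{s['n_components']} PCs explain {s['explained_variance_pct']:.1f}%")
    print(f"T2 limit {s['t2_limit']:.2f}; Q limit {s['q_limit']:.3g}")
    print(f"flagged episodes: {s['n_flagged_episodes_t2']} on T2, "
          f"{s['n_flagged_episodes_q']} on Q")
    print(f"test exceedance: {s['test_exceed_t2_pct']:.1f}% (T2), "
          f"{s['test_exceed_q_pct']:.1f}% (Q) — includes the restart points")
    print(f"chart table in {OUT}")
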