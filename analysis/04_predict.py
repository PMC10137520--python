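"""Quality prediction: duplex-split PLS models for lipids and consistency.

Lipids: Savitzky-Golay 2nd derivative + mean centering, latent variables
chosen by 10-split venetian-blinds RMSECV, VIP scores locating the
informative oil bands.  Consistency: Dynamic Orthogonal Projection on raw
spectra (the response is carried by scatter behaviour, not one band),
mean centering only afterwards.  Anomalous restart samples are removed from
the test set after splitting.  Models, RMSECV curves, VIP tables and
predictions go to ``results/predict/<response>/``.
"""

from pathlib import Path

from procmon.pipeline import RunConfig, run_pipeline
from procmon.synthetic import CampaignConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "predict"

if __name__ == "__main__":
    for response in ("lipids", "consistency"):
        report = run_pipeline(
            RunConfig(stage="predict", response=response,
                      campaign=CampaignConfig(), out_dir=OUT / response, seed=2020)
        )
        s = report.summary
        unit = "%" if response == "lipids" else "cm"
        print(f"{response}: {s['n_calibration']} cal / {s['n_test']} test "
              f"({s['n_anomalous_removed_from_test']} anomalous removed), "
              f"DOP={'on' if s['dop'] else 'off'}")
        print(f"  {s['selected_lv']} LVs, RMSECV {s['rmsecv']:.3f} {unit}, "
              f"RMSEP {s['rmsep']:.3f} {unit}, "
              f"VIP max at {s['vip_max_wavelength_nm']:.0f} nm")
    print(f"tables in {OUT}")
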