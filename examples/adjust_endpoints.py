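"""Adjusted p-values for a multi-endpoint dose-response dataset.

Simulates a carcinogenicity-style study — 200 animals split over doses
{0, 2.5, 5, 10}, five binary tumor endpoints with within-family correlation
0.5, two of which truly respond to dose — then compares the three
single-step familywise adjustments on the per-endpoint dose slopes.

If the per-animal NTP methyleugenol table is available at
``data/ntp_methyleugenol.csv`` (see ``data/README.md``), it is analysed
instead, restricted to tumor classes with more than five events.
"""

from pathlib import Path

from multibin import (
    AnalysisConfig,
    generate_scenario,
    regression_scenario,
    run_adjust,
    write_endpoint_csv,
)

ntp = Path(__file__).resolve().parent.parent / "data" / "ntp_methyleugenol.csv"
if ntp.exists():
    path, min_events = str(ntp), 5
    print(f"analysing NTP methyleugenol bioassay ({path})\n")
else:
    scenario = regression_scenario(
        n=200, n_endpoints=5, pi0=0.15, rho=0.5,
        slopes=[0.20, 0.15, 0.0, 0.0, 0.0],
    )
    data = generate_scenario(scenario, seed=7)
    path = "/tmp/multibin_example.csv"
    write_endpoint_csv(data, path)
    min_events = None
    print("analysing a simulated five-endpoint study "
          "(two endpoints truly dose-responsive)\n")

table = run_adjust(
    AnalysisConfig(
        input_path=path,
        design="regression",
        model_class="glm",
        methods=("bonferroni", "mmm", "minp-bootstrap"),
        B=2000,
        seed=1,
        min_events=min_events,
    )
)

wide = table.pivot_table(
    index="endpoint", columns="method", values="p_adj"
).round(4)
print(wide.to_string())
print(
    "\nEach cell is that endpoint's dose-slope p-value after familywise "
    "adjustment.\nBonferroni ignores the correlation between endpoints and is "
    "most conservative;\nthe joint-normal (mmm) adjustment exploits the "
    "estimated correlation; the minP\nbootstrap resamples whole response rows "
    "and is typically smallest while still\ncontrolling the familywise error "
    "rate."
)
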