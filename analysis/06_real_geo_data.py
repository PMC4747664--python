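"""Optional real-data rerun on user-downloaded GEO files.

The six accessions analyzed by the study (GSE5093, GSE3500, GSE4024,
GSE1898, GSE65484, GSE65485) are not redistributed here. To rerun a
dataset, download its series matrix or per-array spot tables from GEO,
place a YAML pipeline config at data/geo/<ACCESSION>.yaml (see
`sdig.pipeline.PipelineConfig.from_yaml`; `sdig.pipeline.PRESETS` gives
the per-accession mode and pairing), and run this script. Each configured
dataset is processed end to end and its summary row is appended to
results/geo_summary.tsv.

Without any configs the script lists what it would do and exits cleanly.
"""
from pathlib import Path

from sdig import io as sio
from sdig.pipeline import PRESETS, PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
CONFIG_DIR = ROOT / "data" / "geo"
OUT = ROOT / "results"


def main() -> None:
    configs = sorted(CONFIG_DIR.glob("*.yaml")) if CONFIG_DIR.exists() else []
    if not configs:
        print(f"no dataset configs under {CONFIG_DIR}; nothing to do.")
        print("expected accessions and modes:")
        for accession, preset in PRESETS.items():
            structure = "paired" if preset.paired else "non-paired"
            print(f"  {accession}: mode={preset.mode} ({structure})")
        return
    rows = []
    for path in configs:
        cfg = PipelineConfig.from_yaml(path)
        rep = run_pipeline(cfg, out_dir=OUT / "geo" / cfg.dataset_id)
        rows.append(rep["row"])
        row = rep["row"]
        print(f"{row['dataset']}: Q={row['Q']} T={row['T_pct']:.2f}% "
              f"mean_normal={row['mean_normal']:.4f} "
              f"mean_tumor={row['mean_tumor']:.4f} p={row['p_value']:.3g}")
    sio.write_summary_table(rows, OUT / "geo_summary.tsv")


if __name__ == "__main__":
    main()
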