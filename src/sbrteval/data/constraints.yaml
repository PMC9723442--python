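# Clinical dose-volume requirements and constraints for 50 Gy / 5 fx
# bilateral-lung SBRT plan evaluation.
# "structure: ptv" applies to each of ptv1, ptv2, ptv12.
# The "~" comparator is a soft band (pass within +/- band of the threshold);
# all other comparators are strict as written.
- {structure: ptv, metric: coverage, cmp: ">=", threshold: 95.0, units: "%"}
- {structure: ptv, metric: pidl, cmp: "~", threshold: 70.0, units: "%", band: 10.0}
- {structure: lungs, metric: "v_pct@5", cmp: "<", threshold: 60.0, units: "%"}
- {structure: lungs, metric: "v_pct@20", cmp: "<", threshold: 25.0, units: "%"}
- {structure: lungs, metric: "v_below_cc@12.5", cmp: ">", threshold: 1500.0, units: "cc"}
- {structure: lungs, metric: "v_below_cc@13.5", cmp: ">", threshold: 1000.0, units: "cc"}
- {structure: heart, metric: d_max, cmp: "<", threshold: 38.0, units: "Gy"}
- {structure: heart, metric: d_mean, cmp: "<", threshold: 12.0, units: "Gy"}
- {structure: heart, metric: "v_cc@32", cmp: "<", threshold: 15.0, units: "cc"}
- {structure: cord, metric: d_max, cmp: "<", threshold: 27.0, units: "Gy"}
- {structure: cord, metric: "d_cc@0.25", cmp: "<", threshold: 22.0, units: "Gy"}
- {structure: cord, metric: "d_cc@1.2", cmp: "<", threshold: 13.5, units: "Gy"}
- {structure: trachea, metric: d_max, cmp: "<", threshold: 40.0, units: "Gy"}
- {structure: trachea, metric: "v_cc@16.5", cmp: "<", threshold: 4.0, units: "cc"}
- {structure: bronchus, metric: d_max, cmp: "<", threshold: 40.0, units: "Gy"}
- {structure: bronchus, metric: "v_cc@16.5", cmp: "<", threshold: 4.0, units: "cc"}
- {structure: esophagus, metric: d_max, cmp: "<", threshold: 35.0, units: "Gy"}
- {structure: esophagus, metric: "v_cc@19.5", cmp: "<", threshold: 5.0, units: "cc"}
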