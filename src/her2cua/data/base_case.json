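{
  "distributions": {
    "cost.ef_dmc_gt10": {
      "family": "gamma",
      "mean": 404.15,
      "se": 40.42
    },
    "cost.ef_dmc_y1.s1": {
      "family": "gamma",
      "mean": 66740.23,
      "se": 6674.02
    },
    "cost.ef_dmc_y1.s2": {
      "family": "gamma",
      "mean": 66819.49,
      "se": 6681.95
    },
    "cost.ef_dmc_y1.s3": {
      "family": "gamma",
      "mean": 66740.23,
      "se": 6674.02
    },
    "cost.ef_dmc_y1.s4": {
      "family": "gamma",
      "mean": 576956.06,
      "se": 57695.61
    },
    "cost.ef_dmc_y1.s5": {
      "family": "gamma",
      "mean": 157203.06,
      "se": 15720.31
    },
    "cost.ef_dmc_y2_5": {
      "family": "gamma",
      "mean": 1097.03,
      "se": 109.7
    },
    "cost.ef_dmc_y6_10": {
      "family": "gamma",
      "mean": 876.94,
      "se": 87.69
    },
    "cost.ef_dnmc_later": {
      "family": "gamma",
      "mean": 1768.42,
      "se": 176.84
    },
    "cost.ef_dnmc_y1": {
      "family": "gamma",
      "mean": 9045.57,
      "se": 904.56
    },
    "cost.lrr_dmc_later": {
      "family": "gamma",
      "mean": 263124.47,
      "se": 26312.44
    },
    "cost.lrr_dmc_y1": {
      "family": "gamma",
      "mean": 307205.83,
      "se": 30720.58
    },
    "cost.lrr_dnmc": {
      "family": "gamma",
      "mean": 103098.78,
      "se": 10309.88
    },
    "cost.met_dmc": {
      "family": "gamma",
      "mean": 111356.35,
      "se": 11135.63
    },
    "cost.met_dnmc": {
      "family": "gamma",
      "mean": 9172.73,
      "se": 917.27
    },
    "cost.neoadj_dmc.s1": {
      "family": "gamma",
      "mean": 403337.46,
      "se": 40333.75
    },
    "cost.neoadj_dmc.s2": {
      "family": "gamma",
      "mean": 2591980.99,
      "se": 259198.1
    },
    "cost.neoadj_dmc.s3": {
      "family": "gamma",
      "mean": 712164.1,
      "se": 71216.41
    },
    "cost.neoadj_dmc.s4": {
      "family": "gamma",
      "mean": 2591980.99,
      "se": 259198.1
    },
    "cost.neoadj_dmc.s5": {
      "family": "gamma",
      "mean": 712164.1,
      "se": 71216.41
    },
    "cost.neoadj_dnmc": {
      "family": "gamma",
      "mean": 61575.58,
      "se": 6157.56
    },
    "cost.rem_dmc_gt10": {
      "family": "gamma",
      "mean": 664.71,
      "se": 66.47
    },
    "cost.rem_dmc_y1": {
      "family": "gamma",
      "mean": 67429.98,
      "se": 6743.0
    },
    "cost.rem_dmc_y2_5": {
      "family": "gamma",
      "mean": 742.72,
      "se": 74.27
    },
    "cost.rem_dmc_y6_10": {
      "family": "gamma",
      "mean": 1137.5,
      "se": 113.75
    },
    "cost.rem_dnmc_later": {
      "family": "gamma",
      "mean": 1768.42,
      "se": 176.84
    },
    "cost.rem_dnmc_y1": {
      "family": "gamma",
      "mean": 6189.48,
      "se": 618.95
    },
    "hr.s2": {
      "ci_high": 0.91,
      "ci_low": 0.32,
      "family": "lognormal",
      "mean": 0.54
    },
    "hr.s3": {
      "ci_high": 1.22,
      "ci_low": 0.6,
      "family": "lognormal",
      "mean": 0.85
    },
    "hr.s4": {
      "ci_high": 0.91,
      "ci_low": 0.32,
      "family": "lognormal",
      "mean": 0.54
    },
    "hr.s5": {
      "ci_high": 1.22,
      "ci_low": 0.6,
      "family": "lognormal",
      "mean": 0.85
    },
    "mort.age_50_54": {
      "family": "beta",
      "mean": 0.00027,
      "se": 3e-05
    },
    "mort.age_55_59": {
      "family": "beta",
      "mean": 0.00041,
      "se": 4e-05
    },
    "mort.age_60_64": {
      "family": "beta",
      "mean": 0.00067,
      "se": 7e-05
    },
    "mort.age_65_69": {
      "family": "beta",
      "mean": 0.0012,
      "se": 0.00012
    },
    "mort.age_70_74": {
      "family": "beta",
      "mean": 0.00226,
      "se": 0.00023
    },
    "mort.age_75_79": {
      "family": "beta",
      "mean": 0.00379,
      "se": 0.00038
    },
    "mort.age_80_84": {
      "family": "beta",
      "mean": 0.00708,
      "se": 0.00071
    },
    "mort.age_85_plus": {
      "family": "beta",
      "mean": 0.00708,
      "se": 0.00071
    },
    "tp.ef_event.adjuvant_t": {
      "family": "beta",
      "mean": 0.01015,
      "se": 0.00102
    },
    "tp.ef_event.after_60m": {
      "family": "beta",
      "mean": 0.01015,
      "se": 0.00102
    },
    "tp.ef_event.s4.year1": {
      "family": "beta",
      "mean": 0.00118,
      "se": 0.00012
    },
    "tp.ef_event.s4.year2": {
      "family": "beta",
      "mean": 0.00229,
      "se": 0.00023
    },
    "tp.ef_event.s4.year3": {
      "family": "beta",
      "mean": 0.0022,
      "se": 0.00022
    },
    "tp.ef_event.s4.year4": {
      "family": "beta",
      "mean": 0.0022,
      "se": 0.00022
    },
    "tp.ef_event.s5": {
      "family": "beta",
      "mean": 0.00798,
      "se": 0.0008
    },
    "tp.event_split_lrr": {
      "family": "beta",
      "mean": 0.25,
      "se": 0.025
    },
    "tp.lrr_to_death": {
      "family": "beta",
      "mean": 0.01064,
      "se": 0.00106
    },
    "tp.lrr_to_met": {
      "family": "beta",
      "mean": 0.02317,
      "se": 0.00232
    },
    "tp.lrr_to_rem": {
      "family": "beta",
      "mean": 0.96619,
      "se": 0.09662
    },
    "tp.met_to_death": {
      "family": "beta",
      "mean": 0.04672,
      "se": 0.00467
    },
    "tp.rem_to_met": {
      "family": "beta",
      "mean": 0.0076,
      "se": 0.00076
    },
    "util.ef_after_year1": {
      "family": "beta",
      "mean": 0.85,
      "se": 0.0102
    },
    "util.ef_year1": {
      "family": "beta",
      "mean": 0.81,
      "se": 0.0183
    },
    "util.lrr": {
      "family": "beta",
      "mean": 0.72,
      "se": 0.0198
    },
    "util.metastasis": {
      "family": "beta",
      "mean": 0.7,
      "se": 0.0266
    },
    "util.remission": {
      "family": "beta",
      "mean": 0.82,
      "se": 0.0174
    }
  },
  "efficacy_mode": "hr_on_baseline",
  "schema": "her2cua-model/1",
  "settings": {
    "discount_rate_costs": 0.03,
    "discount_rate_outcomes": 0.03,
    "horizon_age_years": 100.0,
    "lkr_per_usd": 194.78,
    "start_age_years": 50.0,
    "wtp_lkr": 758680.0
  },
  "values": {
    "cost.ef_dmc_gt10": 404.15,
    "cost.ef_dmc_y1.s1": 66740.23,
    "cost.ef_dmc_y1.s2": 66819.49,
    "cost.ef_dmc_y1.s3": 66740.23,
    "cost.ef_dmc_y1.s4": 576956.06,
    "cost.ef_dmc_y1.s5": 157203.06,
    "cost.ef_dmc_y2_5": 1097.03,
    "cost.ef_dmc_y6_10": 876.94,
    "cost.ef_dnmc_later": 1768.42,
    "cost.ef_dnmc_y1": 9045.57,
    "cost.lrr_dmc_later": 263124.47,
    "cost.lrr_dmc_y1": 307205.83,
    "cost.lrr_dnmc": 103098.78,
    "cost.met_dmc": 111356.35,
    "cost.met_dnmc": 9172.73,
    "cost.neoadj_dmc.s1": 403337.46,
    "cost.neoadj_dmc.s2": 2591980.99,
    "cost.neoadj_dmc.s3": 712164.1,
    "cost.neoadj_dmc.s4": 2591980.99,
    "cost.neoadj_dmc.s5": 712164.1,
    "cost.neoadj_dnmc": 61575.58,
    "cost.rem_dmc_gt10": 664.71,
    "cost.rem_dmc_y1": 67429.98,
    "cost.rem_dmc_y2_5": 742.72,
    "cost.rem_dmc_y6_10": 1137.5,
    "cost.rem_dnmc_later": 1768.42,
    "cost.rem_dnmc_y1": 6189.48,
    "hr.s2": 0.54,
    "hr.s3": 0.85,
    "hr.s4": 0.54,
    "hr.s5": 0.85,
    "mort.age_50_54": 0.00027,
    "mort.age_55_59": 0.00041,
    "mort.age_60_64": 0.00067,
    "mort.age_65_69": 0.0012,
    "mort.age_70_74": 0.00226,
    "mort.age_75_79": 0.00379,
    "mort.age_80_84": 0.00708,
    "mort.age_85_plus": 0.00708,
    "tp.ef_event.adjuvant_t": 0.01015,
    "tp.ef_event.after_60m": 0.01015,
    "tp.ef_event.s4.year1": 0.00118,
    "tp.ef_event.s4.year2": 0.00229,
    "tp.ef_event.s4.year3": 0.0022,
    "tp.ef_event.s4.year4": 0.0022,
    "tp.ef_event.s5": 0.00798,
    "tp.event_split_lrr": 0.25,
    "tp.lrr_to_death": 0.01064,
    "tp.lrr_to_met": 0.02317,
    "tp.lrr_to_rem": 0.96619,
    "tp.met_to_death": 0.04672,
    "tp.rem_to_met": 0.0076,
    "util.ef_after_year1": 0.85,
    "util.ef_year1": 0.81,
    "util.lrr": 0.72,
    "util.metastasis": 0.7,
    "util.remission": 0.82
  }
}
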