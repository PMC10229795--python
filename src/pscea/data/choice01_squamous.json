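{
 "population": "squamous",
 "settings": {},
 "survival": {
  "placebo": {
   "os": {
    "intercept": 3.09,
    "log_scale": -0.851,
    "time_unit": "months"
   },
   "pfs": {
    "intercept": 1.995,
    "log_scale": -0.621,
    "time_unit": "months"
   }
  },
  "toripalimab": {
   "os": {
    "intercept": 3.23,
    "log_scale": -0.308,
    "time_unit": "months"
   },
   "pfs": {
    "intercept": 2.463,
    "log_scale": -0.263,
    "time_unit": "months"
   }
  }
 },
 "costs": [
  {
   "name": "toripalimab",
   "base_value": 342,
   "low": 239,
   "high": 445,
   "distribution": "gamma",
   "application": "per_cycle",
   "state": "PFS",
   "arm": "toripalimab",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": 30.4375,
   "group": null
  },
  {
   "name": "chemotherapy",
   "base_value": 313,
   "low": 220,
   "high": 408,
   "distribution": "gamma",
   "application": "per_cycle",
   "state": "PFS",
   "arm": "both",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": 30.4375,
   "group": null
  },
  {
   "name": "tests_placebo",
   "base_value": 420,
   "low": 294,
   "high": 546,
   "distribution": "gamma",
   "application": "per_cycle",
   "state": "PFS",
   "arm": "placebo",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": 30.4375,
   "group": null
  },
  {
   "name": "tests_toripalimab",
   "base_value": 439,
   "low": 307,
   "high": 571,
   "distribution": "gamma",
   "application": "per_cycle",
   "state": "PFS",
   "arm": "toripalimab",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": 30.4375,
   "group": null
  },
  {
   "name": "pd_treatment_placebo",
   "base_value": 342,
   "low": 239,
   "high": 445,
   "distribution": "gamma",
   "application": "per_cycle",
   "state": "PD",
   "arm": "placebo",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": 30.4375,
   "group": null
  },
  {
   "name": "pd_treatment_toripalimab",
   "base_value": 299,
   "low": 209,
   "high": 389,
   "distribution": "gamma",
   "application": "per_cycle",
   "state": "PD",
   "arm": "toripalimab",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": 30.4375,
   "group": null
  },
  {
   "name": "ae_management_placebo",
   "base_value": 138,
   "low": 97,
   "high": 179,
   "distribution": "gamma",
   "application": "one_off",
   "state": "PFS",
   "arm": "placebo",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": null,
   "group": null
  },
  {
   "name": "ae_management_toripalimab",
   "base_value": 140,
   "low": 98,
   "high": 182,
   "distribution": "gamma",
   "application": "one_off",
   "state": "PFS",
   "arm": "toripalimab",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": null,
   "group": null
  },
  {
   "name": "hospitalization_pfs",
   "base_value": 50,
   "low": 35,
   "high": 65,
   "distribution": "gamma",
   "application": "per_cycle",
   "state": "PFS",
   "arm": "both",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": 30.4375,
   "group": "hospitalization"
  },
  {
   "name": "hospitalization_pd",
   "base_value": 50,
   "low": 35,
   "high": 65,
   "distribution": "gamma",
   "application": "per_cycle",
   "state": "PD",
   "arm": "both",
   "start_cycle": 0,
   "stop_cycle": null,
   "interval_days": 30.4375,
   "group": "hospitalization"
  }
 ],
 "utilities": {
  "pfs": {
   "value": 0.673,
   "low": 0.47,
   "high": 0.87,
   "distribution": "beta"
  },
  "pd": {
   "value": 0.473,
   "low": 0.33,
   "high": 0.61,
   "distribution": "beta"
  },
  "death": 0.0
 }
}
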