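{
 "schema_version": 1,
 "comment": "Reference kinetic fixtures. Rates in 1/ms at 0 mV, charges in e0, voltages in mV. 'act' aggregates DI-DIII activation (one closed->open step per row); 'div' is the DIV sensor step; 'ifm' the motif binding step; 'gate' the final S6 gate closure. 'act67' overrides the open<->closed step of the gate-closed (inactivated) row.",
 "base": {
  "act": {
   "k0f": 1.295,
   "zf": 0.835,
   "k0b": 0.07465,
   "zb": -1.165,
   "q": 2.33
  },
  "div": {
   "k0f": 0.2396,
   "zf": 0.8,
   "k0b": 0.1104,
   "zb": -0.783,
   "q": 2.67
  },
  "ifm": {
   "kon": 3.0,
   "koff": 2.5
  },
  "gate": {
   "kc": 8.0,
   "ko": 0.1,
   "z": 0.3,
   "q": 0.6,
   "open_scale": 0.3
  },
  "act67": {
   "scale": 1.0,
   "shift_mV": 0.0
  },
  "act_shift_mV": 0.0,
  "div_shift_mV": 0.0,
  "open_pnak": 11.0,
  "leak_pna": 0.0,
  "inact_pnak": 4.0,
  "coupling": 1.0,
  "n_channels": 1000000000.0,
  "p_abs": 1e-15,
  "cap_nF": 20.0,
  "clamp_tau_ms": 0.075
 },
 "fixtures": {
  "WT": {
   "overrides": {},
   "targets": {
    "iss_over_ipeak_60mV_max": 0.03,
    "immobilized_fraction": 0.6,
    "open_pnak": 11.0,
    "inactivated_conductance": 0.0
   }
  },
  "I1284A": {
   "overrides": {
    "act_shift_mV": 13.5,
    "div_shift_mV": 10.0
   },
   "targets": {
    "gv_shift_mV": 15.2,
    "hinf_shift_mV": 10.0,
    "iss_over_ipeak_60mV_max": 0.03
   }
  },
  "I1288A": {
   "overrides": {
    "act_shift_mV": 9.2,
    "div_shift_mV": 10.0
   },
   "targets": {
    "gv_shift_mV": 9.6,
    "hinf_shift_mV": 10.0,
    "iss_over_ipeak_60mV_max": 0.03
   }
  },
  "DIIIAA": {
   "overrides": {
    "act_shift_mV": 0.0,
    "div_shift_mV": 12.0,
    "leak_pna": 0.3,
    "inact_pnak": 4.0,
    "act67": {
     "scale": 0.6,
     "shift_mV": -17.0
    },
    "ifm": {
     "kon": 3.0,
     "koff": 4.0
    },
    "act": {
     "k0f": 0.741,
     "zf": 1.064,
     "k0b": 0.1574,
     "zb": -0.936,
     "q": 2.33,
     "scale": 1.0
    }
   },
   "targets": {
    "open_pnak": 11.0,
    "leak_pnak": 4.0,
    "iss_over_ipeak_60mV": 0.2,
    "qv_shift_mV": 8.5,
    "gv_steady_shift_mV": -8.5,
    "hinf_shift_mV": 10.0,
    "immobilized_fraction": 0.6,
    "tail_tau_fast_ms": 0.3,
    "tail_tau_weighted_late_ms": 0.8
   }
  },
  "DIVAA": {
   "overrides": {
    "open_pnak": 13.0,
    "leak_pna": 0.16,
    "inact_pnak": 2.0,
    "act67": {
     "scale": 0.35,
     "shift_mV": 0.0
    }
   },
   "targets": {
    "open_pnak": 13.0,
    "leak_pnak": 2.0,
    "iss_over_ipeak_60mV": 0.13,
    "immobilized_fraction": 0.6
   }
  },
  "DIII_IVAA": {
   "overrides": {
    "act_shift_mV": 0.0,
    "div_shift_mV": 12.0,
    "open_pnak": 2.4,
    "leak_pna": 0.3,
    "inact_pnak": 1.5,
    "act67": {
     "scale": 0.6,
     "shift_mV": -17.0
    },
    "ifm": {
     "kon": 3.0,
     "koff": 4.0
    },
    "act": {
     "k0f": 0.741,
     "zf": 1.064,
     "k0b": 0.1574,
     "zb": -0.936,
     "q": 2.33,
     "scale": 1.0
    }
   },
   "targets": {
    "open_pnak": 2.4,
    "leak_pnak": 1.5
   }
  },
  "IQM": {
   "overrides": {
    "gate": {
     "kc": 0.0,
     "ko": 0.45
    },
    "act_shift_mV": 7.0
   },
   "targets": {
    "hinf_base": 1.0,
    "gv_shift_mV": 0.0
   }
  },
  "IQM_DIIIAA": {
   "overrides": {
    "act_shift_mV": 13.0,
    "div_shift_mV": 8.0,
    "gate": {
     "kc": 0.0,
     "ko": 0.45
    }
   },
   "targets": {
    "gv_shift_mV": 9.6,
    "hinf_base": 1.0
   }
  },
  "DIA": {
   "overrides": {
    "act_shift_mV": 12.0,
    "leak_pna": 0.025,
    "inact_pnak": 4.0
   },
   "targets": {
    "gv_shift_mV": 15.0,
    "hinf_base": 0.0
   }
  },
  "DIIAA": {
   "overrides": {
    "coupling": 0.3
   },
   "targets": {
    "coupling": 0.3,
    "iss_over_ipeak_60mV_max": 0.03
   }
  }
 }
}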