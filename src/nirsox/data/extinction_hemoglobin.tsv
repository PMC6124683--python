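# Molar extinction coefficients of deoxy- and oxyhemoglobin at the three
# device wavelengths, linearly interpolated from the standard compiled
# hemoglobin absorption spectra (decadic, tabulated per mole of heme).
# units: eps columns in cm^-1 mM^-1 (decadic); wavelength in nm
wavelength_nm	eps_hb	eps_hbo2
735	1.1090	0.4180
805	0.7618	0.8400
850	0.6913	1.0580
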