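"""Preprocess replicate reflectance measurements of one accession.

Simulates three noisy replicate measurements of a green-flowered accession,
averages them, applies the standard smoothing (9 nm rolling average, three
passes), and reports brightness (area under the curve, a pigment-
concentration proxy) and the chlorophyll call from the 675 nm reflectance
minimum.
"""

import floravision as fv

profile = fv.DEFAULT_CLASS_PROFILES["green"]
replicates = fv.synthetic_data.simulate_replicates(profile, "acc_green_1", n_replicates=3, seed=0)

averaged = fv.average_replicates(replicates)
smoothed = fv.smooth(averaged)  # 9 nm window, 3 passes

print(f"accession:   {smoothed.accession_id}")
print(f"grid:        {smoothed.wavelengths_nm[0]:.0f}-{smoothed.wavelengths_nm[-1]:.0f} nm, "
      f"{smoothed.wavelengths_nm.size} points")
print(f"brightness:  {fv.brightness(smoothed):.1f} reflectance*nm")

call = fv.detect_chlorophyll(smoothed)
print(f"chlorophyll: {'present' if call.present else 'absent'} "
      f"(minimum at {call.minimum_wavelength_nm:.0f} nm, prominence {call.prominence:.3f})")
# The prominence is how far the 675 nm minimum dips below the window
# shoulders: values well above 0.02 are an unambiguous chlorophyll signal.
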