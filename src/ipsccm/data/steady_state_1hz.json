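{"params_hash": "d5a327f084b73709", "n_shells": 20, "cell_radius": 10.0, "pacing_hz": 1.0, "duration_s": 400.0, "converged": true, "threshold": 10.4375, "y": [-63.922748615974314, 0.09843981500618847, 0.08631432074456652, 0.16162157255438575, 0.00010721809841137287, 0.9944793380572137, 0.9061651207876841, 0.9696937339122867, 8.141224833156297e-07, 0.9871821786805939, 0.02112646602280762, 0.26865572979908275, 0.014316589018738463, 0.09784169575517138, 7.313276900929985, 140.5978562933506, 0.2159515286490969, 0.9999999998479703, 0.9999999998474589, 0.99999999984625, 0.9999999998438404, 0.9999999998390378, 0.9999999998288175, 0.9999999998046555, 0.9999999997960698, 0.9999999997937138, 0.9999999997945074, 0.9999999997978074, 0.9999999998029595, 0.9999999998053506, 0.9999999997866155, 0.9999999996735761, 0.9999999989546619, 0.9999999885211239, 0.9999997608946464, 0.9999949752019573, 1.6564408065677442e-08, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 23.74307199181839, 0.00040668892722824773, 0.0004066665605895517, 0.00040661368427105134, 0.0004065089011565989, 0.0004063054609698527, 0.000405911693890596, 0.00040521866438094565, 0.00040494363220215315, 0.00040486569606944836, 0.0004048880263641128, 0.000404985502709581, 0.0004051453497032358, 0.00040537620689521926, 0.0004063922994403551, 0.000414167477963042, 0.0004498680606473552, 0.00037922453062089976, 0.0003076289175500417, 0.00020917123603217926, 8.843802029954537e-05, 0.001327257175834199, 0.0013271884567067375, 0.001327026043280083, 0.0013267042660241803, 0.0013260791375062073, 0.0013248654818922485, 0.0013227158073139131, 0.001321867830923923, 0.0013216283965667322, 0.0013216977683084654, 0.0013219993016817019, 0.0013224910727894646, 0.0013231695676432771, 0.0013261065707297853, 0.0013497954886012781, 0.0014640914669035979, 0.0012426097159313932, 0.001017898975705936, 0.0007012314592104538, 0.0002990243432398323, 0.10351976704517854, 0.10351652242542157, 0.10350886980904953, 0.10349374999538372, 0.10346434819938047, 0.10340625580930768, 0.10329649752635356, 0.10325582025022878, 0.10324457737572199, 0.10324808403384535, 0.10326306675569867, 0.10328740031543801, 0.10331295902956178, 0.10338526334231699, 0.10426471669583899, 0.11117994422081809, 0.09932464137032822, 0.0871984654104182, 0.06637868559195553, 0.031545878698867574, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]}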