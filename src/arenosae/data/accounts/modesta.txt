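20.0–50.0 cm tall, erect or sometimes spreading. Stem scabrous, pubescent in lower part, scabrous, glabrous with sessile glands in upper part; with 4–10 distinct internodes, the uppermost internode 3.0–6.0 cm long and obviously longer than the next upper internode. Cauline leaves oblanceolate 10.0–40.0 × 1.0–4.0 mm, pubescent. Calyx 13.0–15.0 mm long, campanulate at anthesis and clavate in fruit, pubescent, scabrous; teeth unequal; shorter ones 2.0–3.0 mm, ovate, acuminate; longer ones 2.0–4.0 mm, lanceolate, acuminate; marginal hairs long (longer than 0.5 mm), dense. Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 8.0–9.0 mm long, ciliate; limbs 3.0 mm long, bifid, white to pink, lobes oblong, petal limbs cleft to middle or more; coronal scales ca 1.0 mm long, ovate, apex entire or slightly erose. Anthophore 2.5–3.5 mm long, densely puberulent. Anthers included; filaments 6.0–9.0 mm long, glabrous or sparsely pubescent. Styles included. First pedicel 1.0–3.0 cm in flower, 2.0–4.0 cm in fruit, erect, glabrous, apex antrorse. Capsule 9.0–11.0 mm long, oblong or ellipsoid, robust. Seeds 0.6–0.8 mm wide, 0.6–0.7 mm high, testa smooth.
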