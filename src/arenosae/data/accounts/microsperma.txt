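15.0–70.0 cm tall, erect or spreading. Stem pubescent in lower part, scabrous, glabrous but with sessile glands in upper part; with 8–12(–20) distinct internodes, the uppermost internode (3.0–)4.0–6.0(–7.0) cm long and obviously longer than the next upper internode. Basal leaves linear or oblanceolate 1.0–4.0 × 1.0–4.0 mm, pubescent. Cauline leaves linear 10.0–30.0× 1.0–3.0 mm, pubescent. Calyx 9.0–14.0 mm long, campanulate at anthesis and clavate in fruit, pubescent; teeth unequal; shorter ones 2.0–3.0 mm, lanceolate, acuminate; longer ones 2.0–4.0 mm, lanceolate, acuminate; marginal hairs long (longer than 0.5 mm), dense. Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 4.0–7.5 mm long, ciliate; limbs 5.0–6.5 mm long, bifid, upper-surface white or pink, lobes oblong, petal limbs cleft to middle or more; coronal scales 0.8–1.4 mm long, ovate, apex dentate or erose. Anthophore 3.0–5.0 mm long, densely puberulent. Anthers exserted; filaments 6.0–9.0 mm long, sometimes pubescent. Styles exserted. First pedicel 1.0–3.0 cm in flower, 1.0–4.0 cm in fruit, erect, glabrous, apex antrorse. Capsule 6.0–7.0 mm long, oblong, fragile, opaque. Seeds 0.6–1.0 mm wide, 0.4–0.8 mm high, testa smooth or papillate.
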